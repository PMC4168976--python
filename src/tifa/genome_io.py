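"""Genome, annotation and insertion-table I/O, TA-site enumeration and filtering.

Coordinates are 0-based, half-open throughout.  A TA site is identified by
the plus-strand position of its T; a site belongs to a gene iff
``start <= position < end``.  Insertion records reported at ``position`` or
``position + 1`` (the A of the duplex TA, as seen from the minus strand)
collapse onto the same site.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: number of canonical flanking-motif classes: (256 - 16) / 2 + 16
N_MOTIF_CLASSES = 136


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class TASite:
    """One TA dinucleotide locus.

    ``context6`` is the plus-strand 6-mer: two nucleotides upstream, the TA,
    and two nucleotides downstream.  ``motif_class`` is the canonical
    (strand-symmetric) class identifier, or ``None`` when the context
    contains N.  ``excluded`` sites are dropped from all statistics; the
    reason is one of ``"context"`` (N in flanks) or ``"overlap"`` (inside
    two overlapping genes).
    """

    position: int
    context6: str
    motif_class: str | None
    inserted: bool = False
    read_counts: np.ndarray | None = None
    excluded: bool = False
    exclude_reason: str | None = None


@dataclass
class GeneRecord:
    """Annotated gene with its TA sites.

    ``ta_sites`` / ``core_ta_sites`` hold indices into the genome-wide site
    list.  Core sites exclude overlap-excluded loci and the terminal 2% of
    the gene length at the 3' end, where insertions in essential genes are
    tolerated.  ``t_obs`` counts inserted core sites.
    """

    locus_id: str
    start: int
    end: int
    strand: str
    ta_sites: list[int] = field(default_factory=list)
    core_ta_sites: list[int] = field(default_factory=list)
    t_obs: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class InsertionRecord:
    """A mapped transposon insertion with per-sample read counts."""

    position: int
    unique: bool
    read_counts: np.ndarray
    fitness: float | None = None

    @property
    def total_reads(self) -> int:
        return int(self.read_counts.sum())


# ---------------------------------------------------------------------------
# sequence I/O and TA-site enumeration

def read_genome(path: str | Path) -> tuple[str, bool]:
    """Read a single-record FASTA genome.

    Returns the uppercased sequence and a circularity flag, inferred from a
    ``circular`` token in the FASTA description (the convention written by
    :func:`tifa.synthetic.write_genome`).  Raises ``ValueError`` for empty
    files or multi-record FASTA.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise ValueError(f"no FASTA records in {path}")
    if len(records) > 1:
        raise ValueError(
            f"{path} contains {len(records)} records; only single-chromosome "
            "genomes are supported"
        )
    rec = records[0]
    seq = str(rec.seq).upper()
    if not seq:
        raise ValueError(f"empty sequence in {path}")
    if re.search(r"[^ACGTN]", seq):
        raise ValueError("genome contains characters outside ACGTN")
    circular = "circular" in rec.description.lower()
    return seq, circular


def write_genome(path: str | Path, seq: str, name: str = "chromosome",
                 circular: bool = True) -> None:
    desc = "topology=circular" if circular else "topology=linear"
    rec = SeqRecord(Seq(seq), id=name, description=desc)
    SeqIO.write([rec], str(path), "fasta")


def canonical_motif(context6: str) -> str:
    """Canonical class identifier of a 6-mer flanking context.

    The transposon targets the TA duplex, so a context and its reverse
    complement describe the same physical site; the class representative is
    the lexicographically smaller of the two.  Raises ``ValueError`` unless
    the central dinucleotide is TA.
    """
    if len(context6) != 6 or context6[2:4] != "TA":
        raise ValueError(f"not a TA-centred 6-mer: {context6!r}")
    rc = revcomp(context6)
    return context6 if context6 <= rc else rc


def enumerate_motif_classes() -> list[str]:
    """All 136 canonical flanking-motif classes, sorted."""
    classes = {
        canonical_motif(a + b + "TA" + c + d)
        for a, b, c, d in itertools.product("ACGT", repeat=4)
    }
    return sorted(classes)


def find_ta_sites(genome: str, circular: bool = True) -> list[TASite]:
    """Enumerate every plus-strand TA occurrence as a :class:`TASite`.

    Overlapping occurrences (TATA) yield separate sites.  For circular
    genomes the 6-mer context wraps around the origin; for linear genomes
    sites within 2 nt of an end get an N-padded context and are excluded
    from motif statistics (reason ``"context"``) but still counted.
    """
    genome = genome.upper()
    L = len(genome)
    if L < 2:
        return []
    if circular:
        padded = genome[-2:] + genome + genome[:3]
    else:
        padded = "NN" + genome + "NNN"
    sites = []
    for m in re.finditer("(?=TA)", genome):
        p = m.start()
        ctx = padded[p:p + 6]
        if "N" in ctx:
            sites.append(TASite(p, ctx, None, excluded=True,
                                exclude_reason="context"))
        else:
            sites.append(TASite(p, ctx, canonical_motif(ctx)))
    return sites


# ---------------------------------------------------------------------------
# annotation I/O

def read_genes(path: str | Path) -> list[GeneRecord]:
    """Read gene annotations from GFF3 (.gff/.gff3) or 4-column TSV.

    The TSV schema is ``locus_id  start  end  strand`` (0-based half-open,
    tab-delimited, ``#`` comments).  GFF3 coordinates are converted from
    1-based inclusive; the locus is taken from ``locus_tag`` or ``ID``.
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _read_genes_gff3(path)
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["locus_id", "start", "end", "strand"],
                     dtype={"locus_id": str})
    # tolerate a header row
    if len(df) and str(df.iloc[0]["start"]).lstrip("-").isdigit() is False:
        df = df.iloc[1:].reset_index(drop=True)
    genes = [GeneRecord(r.locus_id, int(r.start), int(r.end), str(r.strand))
             for r in df.itertuples()]
    _check_genes(genes)
    return genes


def _read_genes_gff3(path: Path) -> list[GeneRecord]:
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    genes = []
    feature_types = {"gene", "CDS"} & set(db.featuretypes())
    ftype = "gene" if "gene" in feature_types else "CDS"
    for feat in db.features_of_type(ftype, order_by="start"):
        locus = feat.attributes.get("locus_tag", feat.attributes.get("ID", [feat.id]))[0]
        genes.append(GeneRecord(locus, feat.start - 1, feat.end, feat.strand))
    _check_genes(genes)
    return genes


def _check_genes(genes: list[GeneRecord]) -> None:
    for g in genes:
        if g.strand not in "+-":
            raise ValueError(f"gene {g.locus_id}: bad strand {g.strand!r}")
        if g.end <= g.start and g.end != 0:
            # start > end marks a gene wrapping the origin of a circular
            # chromosome; it is unwrapped in assign_sites_to_genes
            pass


def write_genes(path: str | Path, genes: list[GeneRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("# locus_id\tstart\tend\tstrand\n")
        for g in genes:
            fh.write(f"{g.locus_id}\t{g.start}\t{g.end}\t{g.strand}\n")


def read_insertions(path: str | Path) -> list[InsertionRecord]:
    """Read the mapped-insertion TSV: position, unique(0/1), reads_s1..sK."""
    df = pd.read_csv(path, sep="\t", comment="#")
    read_cols = [c for c in df.columns if c.startswith("reads_")]
    return [
        InsertionRecord(int(r["position"]), bool(int(r["unique"])),
                        r[read_cols].to_numpy(dtype=np.int64))
        for _, r in df.iterrows()
    ]


def write_insertions(path: str | Path, records: list[InsertionRecord]) -> None:
    k = len(records[0].read_counts) if records else 4
    cols = [f"reads_s{i + 1}" for i in range(k)]
    with open(path, "w") as fh:
        fh.write("position\tunique\t" + "\t".join(cols) + "\n")
        for r in records:
            fh.write(f"{r.position}\t{int(r.unique)}\t"
                     + "\t".join(str(int(x)) for x in r.read_counts) + "\n")


# ---------------------------------------------------------------------------
# gene/site assignment and insertion filtering

def _gene_intervals(g: GeneRecord, L: int) -> list[tuple[int, int]]:
    """Genomic intervals of a gene, unwrapping origin-spanning genes."""
    if g.end > g.start:
        return [(g.start, g.end)]
    return [(g.start, L), (0, g.end)]  # wraps the origin


def fractional_position(g: GeneRecord, pos: int, L: int) -> float:
    """Position of a site within a gene as a 5'->3' fraction in [0, 1)."""
    if g.end > g.start:
        offset = pos - g.start
        length = g.end - g.start
    else:
        length = (L - g.start) + g.end
        offset = pos - g.start if pos >= g.start else (L - g.start) + pos
    if g.strand == "+":
        return offset / length
    return (length - 1 - offset) / length


def assign_sites_to_genes(genes: list[GeneRecord], sites: list[TASite],
                          genome_length: int,
                          terminal_fraction: float = 0.02) -> None:
    """Attach TA sites to genes and compute core subsets, in place.

    Sites covered by two or more genes are excluded entirely (reason
    ``"overlap"``), following the rule that TA loci in overlapping-gene
    regions are uninterpretable.  Core sites additionally drop the terminal
    ``terminal_fraction`` of the gene length at the 3' end; the 5' end is
    not trimmed.
    """
    L = genome_length
    positions = np.array([s.position for s in sites], dtype=np.int64)
    coverage = np.zeros(L + 1, dtype=np.int32)
    for g in genes:
        for a, b in _gene_intervals(g, L):
            coverage[a] += 1
            coverage[b] -= 1
    coverage = np.cumsum(coverage)[:L]
    overlap_mask = coverage[positions] >= 2
    for s, ov in zip(sites, overlap_mask):
        if ov and not s.excluded:
            s.excluded = True
            s.exclude_reason = "overlap"

    order = np.argsort(positions)
    sorted_pos = positions[order]
    for g in genes:
        idx: list[int] = []
        for a, b in _gene_intervals(g, L):
            lo, hi = np.searchsorted(sorted_pos, [a, b])
            idx.extend(order[lo:hi])
        idx.sort(key=lambda i: fractional_position(g, sites[i].position, L))
        g.ta_sites = idx
        # context-excluded sites (N-padded flanks) stay countable; only
        # overlap-excluded loci leave the dataset entirely
        g.core_ta_sites = [
            i for i in idx
            if sites[i].exclude_reason != "overlap"
            and fractional_position(g, sites[i].position, L) < 1.0 - terminal_fraction
        ]


def filter_insertions(records: list[InsertionRecord], sites: list[TASite],
                      genome: str, min_reads: int = 8,
                      ) -> tuple[list[tuple[int, InsertionRecord]], dict]:
    """Apply the library retention filters.

    A record is retained iff it maps uniquely, its total read count across
    samples is >= ``min_reads`` and it coincides with a TA site (position of
    the T, or of the A for minus-strand reporting).  Returns
    ``(retained, report)`` where ``retained`` pairs each surviving record
    with its site index and ``report`` tallies discards by reason
    (``non_unique`` > ``non_ta`` > ``low_count`` precedence).
    """
    L = len(genome)
    site_by_pos = {s.position: i for i, s in enumerate(sites)}
    report = {"input": len(records), "retained": 0,
              "non_unique": 0, "non_ta": 0, "low_count": 0}
    retained: list[tuple[int, InsertionRecord]] = []
    for r in records:
        if not (0 <= r.position < L):
            raise ValueError(f"insertion position {r.position} beyond genome "
                             f"length {L}")
        if not r.unique:
            report["non_unique"] += 1
            continue
        i = site_by_pos.get(r.position)
        if i is None:
            # minus-strand reporting: position of the A of the duplex TA
            i = site_by_pos.get((r.position - 1) % L)
        if i is None:
            report["non_ta"] += 1
            continue
        if r.total_reads < min_reads:
            report["low_count"] += 1
            continue
        retained.append((i, r))
        report["retained"] += 1
    return retained, report


def combine_samples(retained: list[tuple[int, InsertionRecord]],
                    sites: list[TASite]) -> int:
    """Union the retained records of all samples onto per-site flags.

    A site is inserted if any retained record from any sample maps to it.
    Read counts accumulate across records.  Returns the number of inserted
    sites.
    """
    for i, rec in retained:
        s = sites[i]
        if s.read_counts is None:
            s.read_counts = rec.read_counts.astype(np.int64).copy()
        else:
            s.read_counts = s.read_counts + rec.read_counts
        s.inserted = True
    return sum(1 for s in sites if s.inserted)


def count_observed(genes: list[GeneRecord], sites: list[TASite]) -> None:
    """Fill ``t_obs`` (inserted core sites) for every gene, in place."""
    for g in genes:
        g.t_obs = sum(1 for i in g.core_ta_sites if sites[i].inserted)
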