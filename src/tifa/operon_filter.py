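"""Polar-effect screening of essential calls using operon structure.

A transcriptionally terminated transposon inserted in an upstream operon
gene silences everything downstream, so an apparent essential call may
reflect an essential *downstream* neighbour rather than the gene itself.
An essential call is retained only when the gene is the terminal gene of
its operon, or when its immediately downstream neighbour was itself called
nonessential (so the polarity explanation is ruled out).  Nonessential
calls are unaffected by polarity and always retained.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def read_operons(path: str | Path) -> list[tuple[str, list[str]]]:
    """Operon TSV: operon_id <tab> comma-separated loci in transcription order."""
    operons = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            op_id, members = line.split("\t")
            operons.append((op_id, [m.strip() for m in members.split(",")]))
    return operons


def write_operons(path: str | Path, operons: list[tuple[str, list[str]]]) -> None:
    with open(path, "w") as fh:
        fh.write("# operon_id\tgenes\n")
        for op_id, members in operons:
            fh.write(f"{op_id}\t{','.join(members)}\n")


def polar_filter(calls: dict[str, str],
                 operons: list[tuple[str, list[str]]]) -> pd.DataFrame:
    """Flag essential calls explainable by operon polar effects.

    ``calls`` maps gene id to one of essential / nonessential / conflict /
    unknown.  Genes absent from every operon are treated as monocistronic
    (never flagged).  An unknown downstream neighbour does not rescue an
    upstream essential call (conservative flagging).  Raises ``KeyError``
    when an operon references a gene without a call.

    Returns a frame with gene_id, call, polar_flag, retained.
    """
    downstream: dict[str, str | None] = {}
    for op_id, members in operons:
        for g in members:
            if g not in calls:
                raise KeyError(f"operon {op_id} references unknown gene {g}")
        for i, g in enumerate(members):
            downstream[g] = members[i + 1] if i + 1 < len(members) else None

    rows = []
    for gene, call in calls.items():
        flag = False
        if call == "essential" and gene in downstream:
            nxt = downstream[gene]
            if nxt is not None and calls[nxt] != "nonessential":
                flag = True
        rows.append((gene, call, flag, not flag))
    return pd.DataFrame(rows, columns=["gene_id", "call", "polar_flag",
                                       "retained"])
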