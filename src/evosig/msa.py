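"""Combine the three adaptive-evolution signatures into MSA gene calls.

MSA ("multiple signs of adaptive evolution") genes are those showing at
least two of: a unique amino-acid substitution with functional impact,
elevated root-to-tip divergence, and branch-site positive selection. (The
acronym is the study's term for the gene category, unrelated to "multiple
sequence alignment".)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass
class SignatureRecord:
    orthogroup: str
    gene: str
    unique_sub_impact: bool = False
    divergent: bool = False
    positively_selected: bool = False
    msa: bool | None = None
    details: dict = field(default_factory=dict)

    @property
    def n_signatures(self) -> int:
        return int(self.unique_sub_impact) + int(self.divergent) + int(
            self.positively_selected
        )


def call_msa(records: list[SignatureRecord]) -> list[SignatureRecord]:
    """Set ``msa`` on every record: true iff >= 2 signatures are true.

    Genes absent from any one signature table are represented with that
    signature false; duplicate (orthogroup, gene) rows are an error.
    """
    seen = set()
    out = []
    for rec in records:
        key = (rec.orthogroup, rec.gene)
        if key in seen:
            raise ValueError(f"duplicate record for {key}")
        seen.add(key)
        new = SignatureRecord(
            orthogroup=rec.orthogroup,
            gene=rec.gene,
            unique_sub_impact=bool(rec.unique_sub_impact),
            divergent=bool(rec.divergent),
            positively_selected=bool(rec.positively_selected),
            details=dict(rec.details),
        )
        new.msa = new.n_signatures >= 2
        out.append(new)
    return out


_VENN_CELLS = ("U", "D", "P", "UD", "UP", "DP", "UDP")


def summarize(records: list[SignatureRecord]) -> dict:
    """Counts per signature and per exclusive Venn cell.

    Cell keys: U = unique substitution with impact, D = divergent,
    P = positively selected; "UD" counts genes with exactly U and D, etc.
    """
    summary = {
        "n_genes": len(records),
        "unique_sub_impact": 0,
        "divergent": 0,
        "positively_selected": 0,
        "msa": 0,
        "venn": {cell: 0 for cell in _VENN_CELLS},
    }
    for rec in records:
        if rec.msa is None:
            raise ValueError("records must pass through call_msa first")
        summary["unique_sub_impact"] += rec.unique_sub_impact
        summary["divergent"] += rec.divergent
        summary["positively_selected"] += rec.positively_selected
        summary["msa"] += rec.msa
        cell = (
            ("U" if rec.unique_sub_impact else "")
            + ("D" if rec.divergent else "")
            + ("P" if rec.positively_selected else "")
        )
        if cell:
            summary["venn"][cell] += 1
    return summary


def records_to_frame(records: list[SignatureRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "orthogroup": r.orthogroup,
                "gene": r.gene,
                "unique_sub_impact": r.unique_sub_impact,
                "divergent": r.divergent,
                "positively_selected": r.positively_selected,
                "msa": r.msa,
                **{f"detail_{k}": v for k, v in sorted(r.details.items())},
            }
            for r in records
        ]
    )
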