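"""Design-report writers: TSV (with a '#'-prefixed header block), FASTA, JSON.

Every row of a report is recomputable from its sequence plus the recorded
backend, which the test suite spot-checks.  Reports are 1-based and
greppable; the JSON mirror carries the same content for machines.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import AnnealConfig, DesignGoals, ObjectiveWeights
from .structures import render_dotbracket

COLUMNS = (
    "rank",
    "sequence",
    "structure",
    "dG",
    "neutrality",
    "shape_distance",
    "bp_dist",
    "objective",
    "rank_score",
    "seed",
)


@dataclass
class DesignReport:
    goals: DesignGoals
    weights: ObjectiveWeights
    config: AnnealConfig
    backend_info: str
    master_seed: int
    results: list  # of DesignResult, already ranked

    def header_lines(self) -> list[str]:
        from . import __version__

        g, w, c = self.goals, self.weights, self.config
        return [
            f"# rnaforge {__version__}",
            f"# backend: {self.backend_info}",
            f"# target: {render_dotbracket(g.target_structure)}",
            f"# desired_dG: {g.desired_dG}",
            f"# desired_neutrality: {g.desired_neutrality}",
            f"# weights: neutrality={w.neutrality} dG={w.dG} "
            f"shape={w.shape} bp={w.bp}",
            f"# steps: {c.steps} lookahead: {c.lookahead} "
            f"tie_ends: {c.tie_ends}",
            f"# master_seed: {self.master_seed}",
        ]

    def frame(self) -> pd.DataFrame:
        rows = []
        for rank, r in enumerate(self.results, start=1):
            rows.append(
                {
                    "rank": rank,
                    "sequence": r.sequence,
                    "structure": render_dotbracket(r.predicted.structure),
                    "dG": round(r.predicted.dG, 4),
                    "neutrality": round(r.neutrality.value, 6),
                    "shape_distance": r.shape_distance,
                    "bp_dist": r.bp_dist,
                    "objective": round(r.objective, 6),
                    "rank_score": r.rank_score,
                    "seed": r.seed,
                }
            )
        return pd.DataFrame(rows, columns=COLUMNS)

    def to_tsv(self) -> str:
        body = self.frame().to_csv(sep="\t", index=False)
        return "\n".join(self.header_lines()) + "\n" + body

    def to_json(self) -> str:
        payload = {
            "tool": "rnaforge",
            "backend": self.backend_info,
            "target": render_dotbracket(self.goals.target_structure),
            "desired_dG": self.goals.desired_dG,
            "desired_neutrality": self.goals.desired_neutrality,
            "master_seed": self.master_seed,
            "designs": self.frame().to_dict(orient="records"),
        }
        return json.dumps(payload, indent=2)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_tsv())

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())


def write_fasta(results: list, path) -> None:
    """FASTA records ``design_<rank>`` with dG/neutrality/shape_dist in the
    description; raises on an empty result list."""
    if not results:
        raise ValueError("no results to write")
    records = []
    for rank, r in enumerate(results, start=1):
        records.append(
            SeqRecord(
                Seq(r.sequence),
                id=f"design_{rank}",
                description=(
                    f"dG={r.predicted.dG:.2f} "
                    f"neutrality={r.neutrality.value:.4f} "
                    f"shape_dist={r.shape_distance:g}"
                ),
            )
        )
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
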