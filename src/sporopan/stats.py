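"""Summary statistics over a genome-characteristics table.

Rounding follows the precision at which such tables are conventionally
reported: genome size in Mb to 2 decimals, CDS and tRNA counts to the nearest
integer, insertion-sequence (IS) counts to 1 decimal. Extremes are exact.
The prophage column is excluded (it is raw text; see io_formats).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

from .io_formats import GenomeTableRow


@dataclass(frozen=True)
class GenomeTableSummary:
    n_genomes: int
    mean_bp: float
    mean_mb: float
    mean_cds: int
    mean_trnas: int
    mean_is: float
    min_is: int
    max_is: int
    gc_min: float
    gc_max: float

    def as_dict(self) -> dict:
        return asdict(self)


def summarize_genome_table(rows: Sequence[GenomeTableRow]) -> GenomeTableSummary:
    """Arithmetic means (with stated rounding) and extremes per column."""
    if not rows:
        raise ValueError("empty genome table")
    n = len(rows)
    mean_bp = sum(r.genome_bp for r in rows) / n
    is_counts = [r.is_elements for r in rows]
    gcs = [r.gc_percent for r in rows]
    return GenomeTableSummary(
        n_genomes=n,
        mean_bp=mean_bp,
        mean_mb=round(mean_bp / 1e6, 2),
        mean_cds=round(sum(r.cds for r in rows) / n),
        mean_trnas=round(sum(r.trnas for r in rows) / n),
        mean_is=round(sum(is_counts) / n, 1),
        min_is=min(is_counts),
        max_is=max(is_counts),
        gc_min=min(gcs),
        gc_max=max(gcs),
    )
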