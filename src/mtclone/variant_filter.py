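"""Per-variant summary statistics and the threshold filter.

Candidate variants are kept when they strictly exceed all three thresholds:
mean coverage > 5, mean base quality > 27, and allele frequency > 25% in at
least 1% of epithelial cells. The 1% denominator counts epithelial cells with
nonzero coverage at the variant, since AF is undefined without coverage.
Variants selected in more than one patient are excluded everywhere, as
recurrent cross-patient hits are more likely artifacts than independent
somatic events. Homoplasmic germline variants (AF near 1 in nearly every
covered cell) pass the filter by design and are flagged, not removed, so the
somatic lineage stages can set them aside explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import AlleleCountMatrix, CellAnnotation

__all__ = [
    "VariantStats",
    "summarize_variants",
    "filter_variants",
    "flag_homoplasmic",
    "exclude_cross_patient",
]


@dataclass
class VariantStats:
    variant_id: str
    mean_coverage: float
    mean_quality: float  # NaN when no cell has coverage
    af_quantiles: dict[float, float] = field(default_factory=dict)
    frac_epithelial_above: float = 0.0
    af_cut: float = 0.25
    n_cells: int = 0
    n_epithelial_covered: int = 0
    frac_covered_high: float = 0.0  # fraction of covered cells with AF > 0.9

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_epithelial_above <= 1.0:
            raise ValueError("frac_epithelial_above outside [0, 1]")
        if self.mean_coverage < 0:
            raise ValueError("negative mean coverage")


def summarize_variants(
    m: AlleleCountMatrix,
    ann: CellAnnotation,
    af_cut: float = 0.25,
    quantiles: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0),
) -> list[VariantStats]:
    """One :class:`VariantStats` per variant in the matrix.

    Mean coverage averages over every assayed cell; mean quality and all AF
    statistics average only over cells with coverage > 0 (AF is undefined
    otherwise). The epithelial-fraction statistic uses epithelial covered
    cells as its denominator.
    """
    idx = ann.indexed()
    missing = [c for c in m.cell_ids if c not in idx.index]
    if missing:
        raise KeyError(f"cells in matrix absent from annotation: {missing[:5]}")
    is_epi = idx.loc[m.cell_ids, "is_epithelial"].to_numpy()

    af = m.allele_frequency()
    covered = m.coverage > 0
    out: list[VariantStats] = []
    for j, vid in enumerate(m.variant_ids):
        cov_j = covered[:, j]
        n_cov = int(cov_j.sum())
        mean_cov = float(m.coverage[:, j].mean()) if m.n_cells else 0.0
        mean_q = float(np.nanmean(m.base_quality[cov_j, j])) if n_cov else float("nan")
        qdict = (
            {q: float(np.quantile(af[cov_j, j], q)) for q in quantiles} if n_cov else {}
        )
        epi_cov = cov_j & is_epi
        n_epi_cov = int(epi_cov.sum())
        frac = float((af[epi_cov, j] > af_cut).mean()) if n_epi_cov else 0.0
        frac_high = float((af[cov_j, j] > 0.9).mean()) if n_cov else 0.0
        out.append(
            VariantStats(
                variant_id=vid,
                mean_coverage=mean_cov,
                mean_quality=mean_q,
                af_quantiles=qdict,
                frac_epithelial_above=frac,
                af_cut=af_cut,
                n_cells=m.n_cells,
                n_epithelial_covered=n_epi_cov,
                frac_covered_high=frac_high,
            )
        )
    return out


def filter_variants(
    stats: list[VariantStats],
    min_mean_cov: float = 5.0,
    min_mean_q: float = 27.0,
    af_cut: float = 0.25,
    min_frac_epi: float = 0.01,
) -> list[str]:
    """Variants strictly exceeding all three thresholds.

    ``af_cut`` must match the cut the statistics were computed with; a NaN
    mean quality (no covered cell) never passes.
    """
    out = []
    for s in stats:
        if s.af_cut != af_cut:
            raise ValueError(
                f"variant {s.variant_id!r} summarized at af_cut={s.af_cut}, "
                f"filter called with af_cut={af_cut}"
            )
        if (
            s.mean_coverage > min_mean_cov
            and np.isfinite(s.mean_quality)
            and s.mean_quality > min_mean_q
            and s.frac_epithelial_above > min_frac_epi
        ):
            out.append(s.variant_id)
    return out


def flag_homoplasmic(
    stats: list[VariantStats], min_frac_high: float = 0.9
) -> list[str]:
    """Variants with AF > 0.9 in at least ``min_frac_high`` of covered cells.

    These are homoplasmic germline variants; they carry no somatic lineage
    information and downstream stages exclude them from clone calling.
    """
    return [s.variant_id for s in stats if s.frac_covered_high >= min_frac_high]


def exclude_cross_patient(
    selected: dict[str, list[str]],
) -> dict[str, list[str]]:
    """Drop any variant appearing in two or more patients' selections."""
    count: dict[str, int] = {}
    for variants in selected.values():
        for v in set(variants):
            count[v] = count.get(v, 0) + 1
    return {
        patient: [v for v in variants if count[v] < 2]
        for patient, variants in selected.items()
    }
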