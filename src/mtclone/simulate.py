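"""Synthetic single-cell data with known clonal ground truth.

The generator emits the three datasets the pipeline consumes — mitochondrial
allele counts, nuclear SNV read counts, and gene-expression counts — together
with the truth tables needed to score every downstream stage:

- *clone cells* draw alt reads at their carried variants from a
  beta-binomial around a high mean heteroplasmy;
- *all other (cell, variant) pairs* draw from the zero-inflated
  beta-binomial background: with probability ``pi0`` exactly zero alt reads,
  otherwise a beta-binomial with small mean ``mu0``. Reference
  (non-epithelial) cells draw from this background everywhere, mirroring
  their role as the null population;
- coverage varies per (cell, variant) as a negative binomial, so the
  coverage-stratified FDR has genuine variation to stratify;
- nuclear SNVs are carried by named clones with a dropout rate, and decoy
  SNVs scatter alt reads independently of any clone;
- expression counts are negative binomial with clone-specific planted
  log2 fold-changes.

The beta-binomial is parameterized by mean ``mu`` and overdispersion ``rho``
via ``alpha = mu (1-rho)/rho``, ``beta = (1-mu)(1-rho)/rho`` — identical to
the fitting module, so parameter-recovery tests compare like with like.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._rng import substream
from .io_formats import (
    AlleleCountMatrix,
    CellAnnotation,
    ExpressionMatrix,
    SNVCountTable,
)

__all__ = [
    "CloneSpec",
    "NoiseSpec",
    "CoverageSpec",
    "DESpec",
    "SNVSpec",
    "ExpressionSpec",
    "SimConfig",
    "SimTruth",
    "default_config",
    "variant_universe",
    "simulate_mito_counts",
    "simulate_snv_counts",
    "simulate_expression",
    "simulate_all",
]

_REFERENCE_TYPES = ("fibroblast", "endothelial", "immune")


@dataclass
class CloneSpec:
    """One clonal population: size, carried variants, heteroplasmy model.

    ``tissue`` may be a single label or a mapping label -> fraction to plant
    a lineage crossing tissue boundaries. ``sample_weights`` optionally biases
    which biopsy of the tissue each clone cell lands in (per-sample gradient).
    """

    clone_id: str
    n_cells: int
    variant_ids: list[str]
    mean_af: float = 0.9
    af_overdispersion: float = 0.05
    tissue: str | dict[str, float] = "BE"
    sample_weights: dict[str, float] | None = None

    def tissue_fractions(self) -> dict[str, float]:
        if isinstance(self.tissue, str):
            return {self.tissue: 1.0}
        total = float(sum(self.tissue.values()))
        return {t: w / total for t, w in self.tissue.items()}


@dataclass
class NoiseSpec:
    """Zero-inflated beta-binomial background noise.

    The defaults are stand-ins for plausible ambient-contamination levels,
    not measurements: pi0 = 0.7 zero inflation, mean background AF 0.005,
    overdispersion 0.05.
    """

    pi0: float = 0.7
    mu0: float = 0.005
    rho0: float = 0.05


@dataclass
class CoverageSpec:
    """Negative-binomial per-(cell, variant) coverage: mean and size r."""

    mean: float = 20.0
    dispersion: float = 5.0


@dataclass
class DESpec:
    """A planted expression effect: gene scaled by 2**log2fc inside a clone."""

    gene_id: str
    log2fc: float
    clone_id: str


@dataclass
class SNVSpec:
    """A nuclear SNV tied to a clone (or a decoy when ``clone_id`` is None).

    Clone cells carry alt reads except for dropouts; decoys scatter alt reads
    over random cells at ``background_rate`` regardless of clone membership.
    """

    snv_id: str
    clone_id: str | None
    dropout_rate: float = 0.3
    background_rate: float = 0.05


@dataclass
class ExpressionSpec:
    """Baseline expression model: gene count, NB size, log-normal gene means."""

    n_genes: int = 200
    nb_dispersion: float = 2.0
    log_mean_loc: float = 1.0
    log_mean_scale: float = 0.5
    cell_size_factor_scale: float = 0.2


@dataclass
class SNVDepthSpec:
    """Negative-binomial per-(cell, SNV) read depth and carrier allele fraction."""

    mean: float = 6.0
    dispersion: float = 2.0
    carrier_vaf: float = 0.5


@dataclass
class SimConfig:
    n_cells: int = 2000
    n_variants: int = 30
    clones: list[CloneSpec] = field(default_factory=list)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    coverage: CoverageSpec = field(default_factory=CoverageSpec)
    fraction_reference_cells: float = 0.25
    samples: dict[str, str] = field(default_factory=dict)  # sample_id -> tissue
    background_tissues: list[str] = field(default_factory=lambda: ["BE"])
    de: list[DESpec] = field(default_factory=list)
    snvs: list[SNVSpec] = field(default_factory=list)
    expression: ExpressionSpec = field(default_factory=ExpressionSpec)
    snv_depth: SNVDepthSpec = field(default_factory=SNVDepthSpec)
    patient_id: str = "P1"
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_cells <= 0 or self.n_variants <= 0:
            raise ValueError("n_cells and n_variants must be positive")
        if not 0.0 <= self.fraction_reference_cells < 1.0:
            raise ValueError("fraction_reference_cells must be in [0, 1)")
        for p, name in ((self.noise.pi0, "pi0"), (self.noise.mu0, "mu0"), (self.noise.rho0, "rho0")):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"noise {name}={p} outside [0, 1]")
        universe = set(variant_universe(self.n_variants))
        n_ref = int(round(self.fraction_reference_cells * self.n_cells))
        n_clone = sum(c.n_cells for c in self.clones)
        if n_clone + n_ref > self.n_cells:
            raise ValueError(
                f"clone cells ({n_clone}) + reference cells ({n_ref}) exceed "
                f"n_cells ({self.n_cells})"
            )
        seen = set()
        for c in self.clones:
            if c.clone_id in seen:
                raise ValueError(f"duplicate clone id {c.clone_id!r}")
            seen.add(c.clone_id)
            if not 0.0 < c.mean_af <= 1.0:
                raise ValueError(f"clone {c.clone_id!r} mean_af must be in (0, 1]")
            if not 0.0 < c.af_overdispersion < 1.0:
                raise ValueError(f"clone {c.clone_id!r} overdispersion must be in (0, 1)")
            for v in c.variant_ids:
                if v not in universe:
                    raise ValueError(
                        f"clone {c.clone_id!r} variant {v!r} not in the simulated "
                        f"universe of {self.n_variants} variants"
                    )
        gene_ids = [d.gene_id for d in self.de]
        if len(set(gene_ids)) != len(gene_ids):
            raise ValueError("duplicate gene ids in DE spec")
        for d in self.de:
            if d.clone_id not in seen:
                raise ValueError(f"DE spec references unknown clone {d.clone_id!r}")
        for s in self.snvs:
            if s.clone_id is not None and s.clone_id not in seen:
                raise ValueError(f"SNV spec references unknown clone {s.clone_id!r}")
            if not 0.0 <= s.dropout_rate <= 1.0:
                raise ValueError(f"SNV {s.snv_id!r} dropout_rate outside [0, 1]")

    def sample_map(self) -> dict[str, str]:
        """Sample -> tissue map; one synthetic biopsy per tissue if unset."""
        if self.samples:
            return dict(self.samples)
        tissues: list[str] = []
        for c in self.clones:
            tissues.extend(c.tissue_fractions())
        tissues.extend(self.background_tissues)
        out = {}
        for t in dict.fromkeys(tissues):
            out[f"S_{t}"] = t
        return out


@dataclass
class SimTruth:
    """Ground truth emitted alongside the simulated matrices."""

    cell_clone: pd.Series  # cell_id -> clone_id or NA
    variant_carriers: dict[str, list[str]]  # variant -> clones carrying it
    true_af: np.ndarray  # cells x variants, drawn per-cell heteroplasmy
    de_table: pd.DataFrame  # gene_id, clone_id, log2fc
    snv_clones: dict[str, str | None]

    def clone_cells(self, clone_id: str) -> list[str]:
        return self.cell_clone.index[self.cell_clone == clone_id].tolist()


def variant_universe(n_variants: int) -> list[str]:
    """Deterministic variant labels spread over the mitochondrial genome."""
    bases = ["G>A", "C>T", "A>G", "T>C"]
    out = []
    for i in range(n_variants):
        pos = 150 + 37 * i
        out.append(f"{pos}{bases[i % 4]}")
    return out


def _beta_params(mu: float, rho: float) -> tuple[float, float]:
    t = (1.0 - rho) / rho
    return mu * t, (1.0 - mu) * t


def _nb_draw(rng: np.random.Generator, mean: float, size_r: float, shape) -> np.ndarray:
    p = size_r / (size_r + mean)
    return rng.negative_binomial(size_r, p, size=shape)


def simulate_mito_counts(
    config: SimConfig,
) -> tuple[AlleleCountMatrix, CellAnnotation, SimTruth]:
    """Draw the mitochondrial allele-count matrix, annotation, and truth."""
    rng = substream(config.seed, "mito")
    n_cells, n_vars = config.n_cells, config.n_variants
    variant_ids = variant_universe(n_vars)
    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]
    vindex = {v: j for j, v in enumerate(variant_ids)}

    n_ref = int(round(config.fraction_reference_cells * n_cells))
    clone_of = np.array([None] * n_cells, dtype=object)
    pos = 0
    for c in config.clones:
        clone_of[pos : pos + c.n_cells] = c.clone_id
        pos += c.n_cells
    ref_start = n_cells - n_ref

    # coverage per (cell, variant)
    coverage = _nb_draw(rng, config.coverage.mean, config.coverage.dispersion, (n_cells, n_vars))

    # background noise everywhere
    a0, b0 = _beta_params(max(config.noise.mu0, 1e-12), config.noise.rho0)
    if config.noise.mu0 > 0:
        p_bg = rng.beta(a0, b0, size=(n_cells, n_vars))
    else:
        p_bg = np.zeros((n_cells, n_vars))
    nonzero = rng.random((n_cells, n_vars)) >= config.noise.pi0
    alt = np.where(nonzero, rng.binomial(coverage, p_bg), 0)

    # clone cells overwrite their carried variants
    true_af = np.zeros((n_cells, n_vars))
    pos = 0
    for c in config.clones:
        rows = np.arange(pos, pos + c.n_cells)
        pos += c.n_cells
        for v in c.variant_ids:
            j = vindex[v]
            if c.mean_af >= 1.0:
                p = np.ones(c.n_cells)
            else:
                a, b = _beta_params(c.mean_af, c.af_overdispersion)
                p = rng.beta(a, b, size=c.n_cells)
            alt[rows, j] = rng.binomial(coverage[rows, j], p)
            true_af[rows, j] = p

    # base quality: high for real signal and noise alike; NaN without coverage
    qual = np.clip(rng.normal(30.0, 2.0, size=(n_cells, n_vars)), 2.0, 41.0)
    qual[coverage == 0] = np.nan

    # annotation: clone cells -> clone tissue; background epithelial cells and
    # reference cells fill the remainder
    sample_map = config.sample_map()
    samples_by_tissue: dict[str, list[str]] = {}
    for s, t in sample_map.items():
        samples_by_tissue.setdefault(t, []).append(s)

    tissue = np.empty(n_cells, dtype=object)
    cell_type = np.empty(n_cells, dtype=object)
    sample_id = np.empty(n_cells, dtype=object)
    is_epi = np.zeros(n_cells, dtype=bool)
    is_ref = np.zeros(n_cells, dtype=bool)

    pos = 0
    for c in config.clones:
        rows = np.arange(pos, pos + c.n_cells)
        pos += c.n_cells
        fracs = c.tissue_fractions()
        labels = list(fracs)
        counts = np.diff(np.round(np.cumsum([0.0] + [fracs[t] for t in labels]) * c.n_cells)).astype(int)
        start = 0
        for t, cnt in zip(labels, counts):
            sub = rows[start : start + cnt]
            start += cnt
            tissue[sub] = t
            cell_type[sub] = f"epithelial_{t}"
            is_epi[sub] = True
            cands = samples_by_tissue.get(t, [f"S_{t}"])
            if c.sample_weights:
                w = np.array([c.sample_weights.get(s, 0.0) for s in cands], dtype=float)
                w = w / w.sum() if w.sum() > 0 else np.full(len(cands), 1 / len(cands))
            else:
                w = np.full(len(cands), 1 / len(cands))
            sample_id[sub] = rng.choice(cands, size=len(sub), p=w)
    # background epithelial cells
    bg_rows = np.arange(pos, ref_start)
    for i, r in enumerate(bg_rows):
        t = config.background_tissues[i % len(config.background_tissues)]
        tissue[r] = t
        cell_type[r] = f"epithelial_{t}"
        is_epi[r] = True
        cands = samples_by_tissue.get(t, [f"S_{t}"])
        sample_id[r] = cands[i % len(cands)]
    # reference cells
    ref_rows = np.arange(ref_start, n_cells)
    all_samples = sorted(sample_map) or ["S_BE"]
    for i, r in enumerate(ref_rows):
        tissue[r] = "stroma"
        cell_type[r] = _REFERENCE_TYPES[i % len(_REFERENCE_TYPES)]
        is_ref[r] = True
        sample_id[r] = all_samples[i % len(all_samples)]

    ann = CellAnnotation(
        pd.DataFrame(
            {
                "cell_id": cell_ids,
                "sample_id": sample_id,
                "patient_id": config.patient_id,
                "tissue": tissue,
                "cell_type": cell_type,
                "is_epithelial": is_epi,
                "is_reference": is_ref,
            }
        )
    )

    carriers: dict[str, list[str]] = {}
    for c in config.clones:
        for v in c.variant_ids:
            carriers.setdefault(v, []).append(c.clone_id)

    truth = SimTruth(
        cell_clone=pd.Series(clone_of, index=pd.Index(cell_ids, name="cell_id")),
        variant_carriers=carriers,
        true_af=true_af,
        de_table=pd.DataFrame(
            [(d.gene_id, d.clone_id, d.log2fc) for d in config.de],
            columns=["gene_id", "clone_id", "log2fc"],
        ),
        snv_clones={s.snv_id: s.clone_id for s in config.snvs},
    )
    m = AlleleCountMatrix(variant_ids, cell_ids, alt, coverage, qual)
    return m, ann, truth


def simulate_snv_counts(config: SimConfig, truth: SimTruth) -> SNVCountTable:
    """Draw the nuclear SNV read-count table (cells with depth > 0 only)."""
    rng = substream(config.seed, "snv")
    cell_ids = truth.cell_clone.index.to_numpy()
    n_cells = len(cell_ids)
    rows = []
    for spec in config.snvs:
        depth = _nb_draw(rng, config.snv_depth.mean, config.snv_depth.dispersion, n_cells)
        if spec.clone_id is not None:
            in_clone = (truth.cell_clone == spec.clone_id).to_numpy()
            carrier = in_clone & (rng.random(n_cells) >= spec.dropout_rate)
        else:
            carrier = rng.random(n_cells) < spec.background_rate
        alt = np.where(carrier, rng.binomial(depth, config.snv_depth.carrier_vaf), 0)
        # a carrier with reads always shows at least one alt read
        alt = np.where(carrier & (depth > 0), np.maximum(alt, 1), alt)
        keep = depth > 0
        rows.append(
            pd.DataFrame(
                {
                    "cell_id": cell_ids[keep],
                    "snv_id": spec.snv_id,
                    "ref_reads": (depth - alt)[keep],
                    "alt_reads": alt[keep],
                }
            )
        )
    if rows:
        df = pd.concat(rows, ignore_index=True)
    else:
        df = pd.DataFrame(columns=SNVCountTable._COLUMNS)
    return SNVCountTable(df)


def simulate_expression(config: SimConfig, truth: SimTruth) -> ExpressionMatrix:
    """Draw NB expression counts with planted clone-specific fold-changes."""
    rng = substream(config.seed, "expr")
    cell_ids = truth.cell_clone.index.to_numpy()
    n_cells = len(cell_ids)
    spec = config.expression
    planted = [d.gene_id for d in config.de]
    n_extra = max(spec.n_genes - len(planted), 0)
    gene_ids = planted + [f"gene{i:04d}" for i in range(n_extra)]
    n_genes = len(gene_ids)

    base = np.exp(rng.normal(spec.log_mean_loc, spec.log_mean_scale, size=n_genes))
    size_factor = np.exp(rng.normal(0.0, spec.cell_size_factor_scale, size=n_cells))
    mean = np.outer(size_factor, base)
    for d in config.de:
        j = gene_ids.index(d.gene_id)
        in_clone = (truth.cell_clone == d.clone_id).to_numpy()
        mean[in_clone, j] *= 2.0 ** d.log2fc
    r = spec.nb_dispersion
    lam = rng.gamma(r, mean / r)
    counts = rng.poisson(lam)
    return ExpressionMatrix(gene_ids, list(cell_ids), sp.csr_matrix(counts))


def simulate_all(config: SimConfig):
    """Run all three generators; returns (allele, annotation, truth, snv, expr)."""
    m, ann, truth = simulate_mito_counts(config)
    snv = simulate_snv_counts(config, truth)
    expr = simulate_expression(config, truth)
    return m, ann, truth, snv, expr


def default_config(seed: int = 0) -> SimConfig:
    """The default multi-clone demonstration world.

    A single-patient, three-tissue biopsy set at a realistic desk scale:
    2,000 cells, 25% non-epithelial reference cells, five clones of 50-120
    cells including one lineage crossing from Barrett's esophagus into
    dysplasia, nested variant sharing for phylogenetic structure, planted
    clone-specific expression changes and clone-linked nuclear SNVs plus
    decoys.
    """
    u = variant_universe(30)
    clones = [
        CloneSpec("cloneA", 120, [u[0]], mean_af=0.9, tissue="squamous"),
        CloneSpec("cloneB", 100, [u[1], u[2]], mean_af=0.85, tissue="cardia"),
        CloneSpec("cloneC", 80, [u[1], u[3]], mean_af=0.85, tissue="cardia"),
        CloneSpec("cloneD", 60, [u[4]], mean_af=0.9, tissue="BE"),
        CloneSpec("cloneE", 50, [u[5]], mean_af=0.95, tissue={"BE": 0.5, "dysplasia": 0.5}),
    ]
    de = [DESpec(f"deg{i:02d}", 1.5 if i % 2 == 0 else -1.5, "cloneE") for i in range(10)]
    snvs = [
        SNVSpec("chr1:1000 A>G", "cloneE", dropout_rate=0.3),
        SNVSpec("chr2:2000 C>T", "cloneA", dropout_rate=0.3),
        SNVSpec("chr3:3000 G>A", None),
        SNVSpec("chr4:4000 T>C", None),
    ]
    return SimConfig(
        n_cells=2000,
        n_variants=30,
        clones=clones,
        background_tissues=["squamous", "cardia", "BE"],
        de=de,
        snvs=snvs,
        seed=seed,
    )
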