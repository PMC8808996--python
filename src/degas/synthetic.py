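"""Splatter-style simulation of single cells and pseudo-bulk patients.

Cells are drawn from a gamma-Poisson (negative binomial) count model:
per-gene base means are Gamma-distributed, each of the four cell types
multiplies a random ~20% subset of genes by log-normal differential-
expression factors, and cell type 4 carries two subtypes (normal /
disease) that add a smaller, sparser subtype-specific factor set on top
of the shared type-4 factors.  Five groups of equal size are generated
(types 1-3, type-4-normal, type-4-disease).  The DE fractions and
factor sizes are calibrated so that unsupervised clustering of the
default cell set finds exactly the four types (the subtypes stay
invisible to clustering but remain linearly separable).

A held-out pool of cells is aggregated into pseudo-bulk "patients": each
patient is the summed counts of ``cells_per_patient`` cells sampled with
replacement from the pool in scenario-specific group proportions.  Three
scenarios encode different disease mechanisms:

* sim1 — disease patients are enriched for cell type 1 (50% vs 25%);
  a purely compositional signal.
* sim2 — disease patients carry the type-4-disease subtype (25%) in
  place of type-4-normal; a purely cell-intrinsic signal.
* sim3 — disease patients are enriched for both type-4 subtypes
  (30% normal + 20% disease); mixed signal.

Normal patients are always 25% of each of the four types.  The 16.6%
entries of the published mixing table are treated as exactly 1/6, and
per-patient integer cell counts are produced by largest-remainder
rounding (so a sim1 disease patient uses 200/66/67/67/0 cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import ExpressionMatrix, LabelSet
from .preprocessing import one_hot_encode

GROUPS = ("type1", "type2", "type3", "type4N", "type4D")
FOUR_TYPES = ("type1", "type2", "type3", "type4")

SIXTH = 1.0 / 6.0
PROPORTIONS: dict[str, dict[str, tuple[float, ...]]] = {
    "sim1": {"disease": (0.5, SIXTH, SIXTH, SIXTH, 0.0),
             "normal": (0.25, 0.25, 0.25, 0.25, 0.0)},
    "sim2": {"disease": (0.25, 0.25, 0.25, 0.0, 0.25),
             "normal": (0.25, 0.25, 0.25, 0.25, 0.0)},
    "sim3": {"disease": (SIXTH, SIXTH, SIXTH, 0.30, 0.20),
             "normal": (0.25, 0.25, 0.25, 0.25, 0.0)},
}

# Which group(s) carry the designed positive disease association.
DISEASE_GROUPS = {"sim1": ("type1",), "sim2": ("type4D",), "sim3": ("type4N", "type4D")}


@dataclass
class SimDesign:
    scenario: str = "sim1"
    n_genes: int = 1000
    cells_per_group: int = 1000          # 5 groups -> 5000 cells total
    holdout_for_patients: int = 2000     # pool used to build patients
    n_patients: int = 600                # half disease, half normal
    cells_per_patient: int = 400
    de_prob: float = 0.10                # fraction of genes DE per cell type
    de_strength: float = 0.5             # log-normal location, type factors
    de_scale: float = 0.4
    subtype_de_strength: float = 0.25    # smaller: subtype separation
    subtype_de_scale: float = 0.3
    subtype_de_prob: float = 0.10
    mean_shape: float = 0.6              # per-gene base mean ~ Gamma
    mean_scale: float = 3.0
    dispersion: float = 0.1              # NB: var = mu + dispersion*mu^2
    libsize_sigma: float = 0.2           # per-cell log-normal library factor
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in PROPORTIONS:
            raise ValueError(f"scenario must be one of {tuple(PROPORTIONS)}")
        if self.holdout_for_patients >= 5 * self.cells_per_group:
            raise ValueError("holdout must be smaller than the total cell count")

    @property
    def n_cells(self) -> int:
        return 5 * self.cells_per_group


def largest_remainder(props, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` by largest remainder; ties go to
    the higher index."""
    props = np.asarray(props, float)
    exact = props / props.sum() * total
    counts = np.floor(exact).astype(int)
    frac = exact - counts
    short = total - counts.sum()
    # ties broken toward higher index: sort by (fraction, index) descending
    order = sorted(range(len(props)), key=lambda j: (frac[j], j), reverse=True)
    for j in order[:short]:
        counts[j] += 1
    return counts


def _group_factors(design: SimDesign, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Multiplicative DE factor vector per group (types share type-4)."""

    def draw(prob: float, loc: float, scale: float) -> np.ndarray:
        f = np.ones(design.n_genes)
        de = rng.random(design.n_genes) < prob
        raw = np.exp(rng.normal(loc, scale, size=design.n_genes))
        down = rng.random(design.n_genes) < 0.5
        raw[down] = 1.0 / raw[down]
        f[de] = raw[de]
        return f

    type_factors = {t: draw(design.de_prob, design.de_strength, design.de_scale)
                    for t in FOUR_TYPES}
    factors = {t: type_factors[t] for t in ("type1", "type2", "type3")}
    for sub in ("type4N", "type4D"):
        extra = draw(design.subtype_de_prob, design.subtype_de_strength,
                     design.subtype_de_scale)
        factors[sub] = type_factors["type4"] * extra
    return factors


def simulate_cells(design: SimDesign) -> tuple[ExpressionMatrix, LabelSet]:
    """Generate the full simulated cell set (5 equal groups, raw counts)."""
    rng = np.random.default_rng([design.seed, 1])
    base = rng.gamma(design.mean_shape, design.mean_scale, size=design.n_genes)
    factors = _group_factors(design, rng)
    blocks, labels = [], []
    for g in GROUPS:
        lib = np.exp(rng.normal(0.0, design.libsize_sigma, size=design.cells_per_group))
        mu = lib[:, None] * (base * factors[g])[None, :]
        shape = 1.0 / design.dispersion
        lam = rng.gamma(shape, mu * design.dispersion)
        blocks.append(rng.poisson(lam).astype(float))
        labels.extend([g] * design.cells_per_group)
    values = np.vstack(blocks)
    ids = [f"cell{i:05d}" for i in range(values.shape[0])]
    genes = [f"gene{j:04d}" for j in range(design.n_genes)]
    X = ExpressionMatrix(values, ids, genes, stage="raw")
    y = one_hot_encode(labels, class_names=list(GROUPS))
    return X, y


def four_type_labels(groups: LabelSet) -> LabelSet:
    """Collapse the type-4 subtypes into a single type-4 class."""
    names = groups.labels()
    collapsed = ["type4" if n in ("type4N", "type4D") else n for n in names]
    return one_hot_encode(collapsed, class_names=list(FOUR_TYPES))


def split_cells(
    cells: ExpressionMatrix, labels: LabelSet, n_holdout: int, seed: int
) -> tuple[tuple[ExpressionMatrix, LabelSet], tuple[ExpressionMatrix, LabelSet]]:
    """Stratified random split into (patient-building pool, cell input).

    Every group appears in both parts; the parts are disjoint and
    exhaustive.  Returns ``((pool_X, pool_y), (input_X, input_y))``.
    """
    rng = np.random.default_rng([seed, 2])
    names = labels.labels()
    group_order = [g for g in GROUPS if g in set(names)] or sorted(set(names))
    sizes = np.array([(names == g).sum() for g in group_order])
    take = largest_remainder(sizes, n_holdout)
    if np.any(take >= sizes) or np.any(take < 1):
        raise ValueError("holdout size leaves a group empty in one of the parts")
    pool_idx: list[int] = []
    for g, k in zip(group_order, take):
        members = np.flatnonzero(names == g)
        pool_idx.extend(rng.choice(members, size=k, replace=False))
    pool_idx = np.sort(np.asarray(pool_idx))
    rest_idx = np.setdiff1d(np.arange(cells.n_samples), pool_idx)
    return (
        (cells.subset_samples(pool_idx), labels.subset(pool_idx)),
        (cells.subset_samples(rest_idx), labels.subset(rest_idx)),
    )


def build_patients(
    pool: ExpressionMatrix,
    pool_labels: LabelSet,
    design: SimDesign,
    return_indices: bool = False,
):
    """Aggregate pool cells into labeled pseudo-bulk patients.

    Each patient sums the raw counts of ``cells_per_patient`` cells drawn
    with replacement from its scenario/status proportions.  Returns
    ``(X_pat, y_pat)`` (+ per-patient sampled indices when requested).
    """
    rng = np.random.default_rng([design.seed, 3])
    names = pool_labels.labels()
    strata = {g: np.flatnonzero(names == g) for g in GROUPS}
    props = PROPORTIONS[design.scenario]
    n_dis = design.n_patients // 2
    statuses = ["disease"] * n_dis + ["normal"] * (design.n_patients - n_dis)
    rows, all_idx = [], []
    for status in statuses:
        counts = largest_remainder(props[status], design.cells_per_patient)
        picked = []
        for g, k in zip(GROUPS, counts):
            if k == 0:
                continue
            if strata[g].size == 0:
                raise ValueError(f"group {g} required by {design.scenario} absent from pool")
            picked.append(rng.choice(strata[g], size=k, replace=True))
        idx = np.concatenate(picked)
        rows.append(pool.values[idx].sum(axis=0))
        all_idx.append(idx)
    ids = [f"pat{i:04d}" for i in range(design.n_patients)]
    X_pat = ExpressionMatrix(np.vstack(rows), ids, list(pool.gene_ids), stage="raw")
    y_pat = one_hot_encode(statuses, class_names=["disease", "normal"])
    if return_indices:
        return X_pat, y_pat, all_idx
    return X_pat, y_pat


def add_subtype_bias(
    X_pat: ExpressionMatrix,
    pool: ExpressionMatrix,
    pool_labels: LabelSet,
    subtype: str,
    n_cells: int = 300,
    multiplier: float = 1000.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Add one fixed rank-1 bias — the summed counts of ``n_cells`` cells
    of one subtype times ``multiplier`` — to every patient, disease and
    normal alike.  Emulates a large systematic domain shift."""
    members = np.flatnonzero(pool_labels.labels() == subtype)
    if members.size == 0:
        raise ValueError(f"subtype {subtype!r} not present in pool")
    rng = np.random.default_rng([seed, 4])
    idx = rng.choice(members, size=n_cells, replace=members.size < n_cells)
    bias = pool.values[idx].sum(axis=0) * multiplier
    return X_pat.with_values(X_pat.values + bias[None, :])


def expected_association(scenario: str, group_names: np.ndarray) -> np.ndarray:
    """Designed per-cell disease association: +1 for the scenario's
    disease group(s), 0 elsewhere."""
    targets = DISEASE_GROUPS[scenario]
    return np.isin(np.asarray(group_names, dtype=object), targets).astype(float)


@dataclass
class SimulatedData:
    """One fully assembled simulation scenario (all matrices raw counts)."""

    design: SimDesign
    cells: ExpressionMatrix           # single-cell input (not used for patients)
    cell_groups: LabelSet             # 5-group labels
    cell_types: LabelSet              # 4-type labels (training target)
    pool: ExpressionMatrix            # held-out cells behind the patients
    pool_groups: LabelSet
    patients: ExpressionMatrix
    patient_labels: LabelSet          # disease/normal
    expected: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def scenario(self) -> str:
        return self.design.scenario


def generate_dataset(design: SimDesign) -> SimulatedData:
    """Run the full generator: cells -> split -> pseudo-patients."""
    cells_all, groups_all = simulate_cells(design)
    (pool, pool_groups), (cells, cell_groups) = split_cells(
        cells_all, groups_all, design.holdout_for_patients, design.seed
    )
    patients, patient_labels = build_patients(pool, pool_groups, design)
    expected = expected_association(design.scenario, cell_groups.labels())
    return SimulatedData(design, cells, cell_groups, four_type_labels(cell_groups),
                         pool, pool_groups, patients, patient_labels, expected)


__all__ = [
    "SimDesign", "SimulatedData", "GROUPS", "FOUR_TYPES", "PROPORTIONS",
    "DISEASE_GROUPS", "largest_remainder", "simulate_cells", "four_type_labels",
    "split_cells", "build_patients", "add_subtype_bias", "expected_association",
    "generate_dataset",
]
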