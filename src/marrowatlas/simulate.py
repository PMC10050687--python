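"""Synthetic multi-study bone-marrow cohorts with planted, recoverable truth.

The generator emulates the statistical structure every downstream stage
assumes, at desk scale:

* several studies, each contributing samples whose donor ages span a wide
  range (default 2-84 years, uniform);
* cell types with disjoint marker-gene sets (elevated mean expression in
  the owning type only);
* per-sample cell-type compositions following logit-linear age trends,
  realised multinomially;
* per-cell-type age genes whose log mean expression changes linearly with
  donor age;
* per-study gene-wise multiplicative (log-normal) batch factors;
* negative-binomial counts with fixed dispersion (Poisson optional).

Query cohorts reuse the reference's structural parameters (gene rates,
markers, age genes, marker boosts) and optionally plant "abnormal" cells:
a fraction of one cell type whose log mean expression is displaced along
a fixed sparse gene-space direction, mimicking an aberrant transcriptional
programme.  All planted structure is returned in a :class:`TruthBundle`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .dataset import CellDataset
from .qc import ConfigurationError

AGE_CENTER = 43.0  # log-mean / logit trends are anchored at this age


@dataclass(frozen=True)
class CellTypeSpec:
    """One simulated cell type.

    ``proportion_age_slope`` acts on the logit of the expected proportion
    (per year); ``age_gene_slope`` is the change in log mean expression
    per year applied to this type's age genes (signs alternate +/- across
    the genes); ``marker_log_fold`` is the natural-log boost of marker
    genes in this type.
    """

    name: str
    base_proportion: float
    proportion_age_slope: float = 0.0
    marker_genes: Tuple[int, ...] = ()
    n_age_genes: int = 0
    age_gene_slope: float = 0.0
    marker_log_fold: float = 2.0


@dataclass(frozen=True)
class CohortConfig:
    """Generator configuration; defaults are the standard study conditions."""

    n_studies: int = 3
    samples_per_study: int = 10
    age_range: Tuple[float, float] = (2.0, 84.0)
    cell_types: Tuple[CellTypeSpec, ...] = ()
    n_genes: int = 300
    batch_sd: float = 0.15
    mean_cells_per_sample: int = 150
    sequencing_depth: float = 2000.0
    dispersion: float = 0.3
    count_model: str = "nb"  # "nb" | "poisson"
    gene_log_rate_sd: float = 1.0
    cell_size_sd: float = 0.2
    n_mito_genes: int = 5
    n_ribo_genes: int = 10
    ages: Optional[Tuple[float, ...]] = None  # discrete list overrides uniform
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cell_types:
            # scalar fields are validated before defaults are derived so
            # errors name the actual offending field
            self.validate()
            object.__setattr__(
                self, "cell_types", tuple(default_cell_types(self.n_genes))
            )
        self.validate()

    def validate(self) -> None:
        def bad(fieldname: str, msg: str):
            raise ConfigurationError(f"CohortConfig.{fieldname}: {msg}")

        if self.n_studies < 1:
            bad("n_studies", "must be a positive integer")
        if self.samples_per_study < 1:
            bad("samples_per_study", "must be a positive integer")
        if not self.age_range[0] < self.age_range[1]:
            bad("age_range", "min must be < max")
        if self.n_genes < 1:
            bad("n_genes", "must be a positive integer")
        if self.batch_sd < 0:
            bad("batch_sd", "must be nonnegative")
        if self.mean_cells_per_sample < 1:
            bad("mean_cells_per_sample", "must be a positive integer")
        if self.sequencing_depth <= 0:
            bad("sequencing_depth", "must be positive")
        if self.dispersion < 0:
            bad("dispersion", "must be nonnegative")
        if self.count_model not in ("nb", "poisson"):
            bad("count_model", "must be 'nb' or 'poisson'")
        total = 0.0
        seen: Set[int] = set()
        for ct in self.cell_types:
            if not 0.0 < ct.base_proportion < 1.0:
                bad("cell_types", f"{ct.name}: base_proportion must be in (0,1)")
            if ct.n_age_genes > self.n_genes:
                bad("cell_types", f"{ct.name}: n_age_genes > n_genes")
            markers = set(ct.marker_genes)
            if markers & seen:
                bad("cell_types", f"{ct.name}: marker_genes overlap another type")
            if markers and max(markers) >= self.n_genes:
                bad("cell_types", f"{ct.name}: marker index out of range")
            seen |= markers
            total += ct.base_proportion
        if self.cell_types and abs(total - 1.0) > 1e-8:
            bad("cell_types", f"base proportions sum to {total:.4f}, expected 1")

    # expected composition at a given age (clipped logit-linear, renormalised)
    def expected_proportions(self, age: float) -> np.ndarray:
        props = []
        for ct in self.cell_types:
            logit = math.log(ct.base_proportion / (1 - ct.base_proportion))
            logit += ct.proportion_age_slope * (age - AGE_CENTER)
            p = 1.0 / (1.0 + math.exp(-logit))
            props.append(min(max(p, 0.001), 0.999))
        arr = np.array(props)
        return arr / arr.sum()


def default_cell_types(n_genes: int, n_types: int = 4,
                       markers_per_type: int = 20,
                       marker_log_fold: float = 2.0,
                       age_genes_per_type: int = 20,
                       age_gene_slope: float = 0.01) -> List[CellTypeSpec]:
    """Standard 4-type configuration with planted trends.

    Mirrors the qualitative marrow picture: one type shrinking with age
    (naive-lymphoid-like), one expanding (effector/memory-like), two flat.
    """
    base = [0.35, 0.30, 0.20, 0.15][:n_types]
    slopes = [-0.010, 0.010, 0.0, 0.0][:n_types]
    names = ["naiveT", "memT", "mono", "progenitor"][:n_types]
    base = [b / sum(base) for b in base]
    # shrink per-type marker / age-gene counts to fit small gene budgets
    # (16 genes are reserved for mito/ribo blocks)
    per_type_budget = max(2, (n_genes - 16) // n_types)
    markers_per_type = max(1, min(markers_per_type, per_type_budget // 2))
    age_genes_per_type = min(age_genes_per_type,
                             per_type_budget - markers_per_type)
    specs = []
    for i in range(n_types):
        lo = i * markers_per_type
        specs.append(
            CellTypeSpec(
                name=names[i],
                base_proportion=base[i],
                proportion_age_slope=slopes[i],
                marker_genes=tuple(range(lo, lo + markers_per_type)),
                n_age_genes=age_genes_per_type,
                age_gene_slope=age_gene_slope,
                marker_log_fold=marker_log_fold,
            )
        )
    return specs


@dataclass
class TruthBundle:
    """Planted ground truth for a generated cohort."""

    sample_ages: Dict[str, float]
    trend_cell_types: Dict[str, float]          # type -> logit slope / year
    age_genes: Dict[Tuple[str, str], float]     # (type, gene_id) -> log slope
    abnormal_cells: Set[str]
    true_labels: Dict[str, str]                 # cell_id -> type
    marker_genes: Dict[str, Tuple[str, ...]] = field(default_factory=dict)
    shift_genes: Dict[str, float] = field(default_factory=dict)  # gene -> delta

    def write(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {"sample_id": list(self.sample_ages), "age_years": list(self.sample_ages.values())}
        ).to_csv(path / "sample_ages.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"cell_type": list(self.trend_cell_types),
             "logit_slope_per_year": list(self.trend_cell_types.values())}
        ).to_csv(path / "trend_cell_types.tsv", sep="\t", index=False)
        rows = [(ct, g, s) for (ct, g), s in self.age_genes.items()]
        pd.DataFrame(rows, columns=["cell_type", "gene_id", "log_slope_per_year"]).to_csv(
            path / "age_genes.tsv", sep="\t", index=False
        )
        pd.DataFrame({"cell_id": sorted(self.abnormal_cells)}).to_csv(
            path / "abnormal_cells.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            {"cell_id": list(self.true_labels), "cell_type": list(self.true_labels.values())}
        ).to_csv(path / "true_labels.tsv", sep="\t", index=False)
        pd.DataFrame(
            [(g, d) for g, d in self.shift_genes.items()],
            columns=["gene_id", "log_mean_delta"],
        ).to_csv(path / "shift_genes.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------
# structural parameters shared by reference and query generation
# ---------------------------------------------------------------------

@dataclass
class _Structure:
    gene_ids: np.ndarray
    symbols: np.ndarray
    base_log_rate: np.ndarray                # (n_genes,)
    type_log_boost: Dict[str, np.ndarray]    # type -> (n_genes,) marker boosts
    age_slopes: Dict[str, np.ndarray]        # type -> (n_genes,) log slopes
    batch_log: np.ndarray                    # (n_studies, n_genes)


def _build_structure(config: CohortConfig) -> _Structure:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    n = config.n_genes
    width = max(4, len(str(n)))
    gene_ids = np.array([f"G{i:0{width}d}" for i in range(n)])
    symbols = gene_ids.astype(object).copy()
    # dedicated mito / ribo symbol blocks at the end of the gene list so
    # they never collide with marker indices (which start at 0)
    mito_idx = np.arange(n - config.n_mito_genes, n) if config.n_mito_genes else np.array([], int)
    ribo_idx = (
        np.arange(n - config.n_mito_genes - config.n_ribo_genes, n - config.n_mito_genes)
        if config.n_ribo_genes else np.array([], int)
    )
    for j, i in enumerate(mito_idx):
        symbols[i] = f"MT-S{j}"
    for j, i in enumerate(ribo_idx):
        symbols[i] = f"RPL-S{j}" if j % 2 == 0 else f"RPS-S{j}"

    base_log_rate = rng.normal(0.0, config.gene_log_rate_sd, size=n)

    type_log_boost: Dict[str, np.ndarray] = {}
    reserved = set()
    for ct in config.cell_types:
        boost = np.zeros(n)
        boost[list(ct.marker_genes)] = ct.marker_log_fold
        type_log_boost[ct.name] = boost
        reserved |= set(ct.marker_genes)
    reserved |= set(mito_idx) | set(ribo_idx)

    # age genes: disjoint across types and from markers / mito / ribo
    free = np.array(sorted(set(range(n)) - reserved))
    age_slopes: Dict[str, np.ndarray] = {}
    for ct in config.cell_types:
        slopes = np.zeros(n)
        if ct.n_age_genes:
            if len(free) < ct.n_age_genes:
                raise ConfigurationError(
                    f"CohortConfig.cell_types: not enough free genes for "
                    f"{ct.name}'s {ct.n_age_genes} age genes"
                )
            pick = rng.choice(free, size=ct.n_age_genes, replace=False)
            signs = np.where(np.arange(ct.n_age_genes) % 2 == 0, 1.0, -1.0)
            slopes[pick] = ct.age_gene_slope * signs
            free = np.array(sorted(set(free) - set(pick)))
        age_slopes[ct.name] = slopes

    batch_log = rng.normal(0.0, config.batch_sd, size=(config.n_studies, n))
    return _Structure(gene_ids, symbols, base_log_rate, type_log_boost,
                      age_slopes, batch_log)


def _draw_counts(rng: np.random.Generator, mean: np.ndarray,
                 config: CohortConfig) -> np.ndarray:
    """NB (gamma-Poisson) or Poisson counts for a (cells x genes) mean."""
    if config.count_model == "poisson" or config.dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / config.dispersion
    lam = rng.gamma(shape, mean * config.dispersion)
    return rng.poisson(lam)


def _generate_cells(config: CohortConfig, struct: _Structure,
                    sample_plan: pd.DataFrame, rng: np.random.Generator,
                    shift: Optional[dict] = None):
    """Generate cells for the samples in ``sample_plan``.

    ``shift`` (query only): dict with keys 'cell_type', 'fraction',
    'delta' (per-gene log-mean displacement vector).
    Returns (counts csr genes x cells, cell_table, true_labels, abnormal).
    """
    names = [ct.name for ct in config.cell_types]
    blocks, cell_rows = [], []
    true_labels: Dict[str, str] = {}
    abnormal: Set[str] = set()
    for row in sample_plan.itertuples():
        n_cells = max(1, rng.poisson(config.mean_cells_per_sample))
        props = config.expected_proportions(row.age_years)
        type_counts = rng.multinomial(n_cells, props)
        sample_cells = []
        cell_no = 0
        for ct, k in zip(config.cell_types, type_counts):
            if k == 0:
                continue
            log_mu = (
                struct.base_log_rate
                + struct.type_log_boost[ct.name]
                + struct.age_slopes[ct.name] * (row.age_years - AGE_CENTER)
                + struct.batch_log[row.study_index]
            )
            flag_abn = np.zeros(k, dtype=bool)
            if shift is not None and ct.name == shift["cell_type"]:
                flag_abn = rng.random(k) < shift["fraction"]
            mu = np.exp(log_mu)
            mu_shift = np.exp(log_mu + shift["delta"]) if shift is not None else mu
            for is_abn in (False, True):
                m = flag_abn == is_abn
                if not m.any():
                    continue
                base = mu_shift if is_abn else mu
                profile = base / base.sum() * config.sequencing_depth
                size = np.exp(rng.normal(0.0, config.cell_size_sd, size=m.sum()))
                cell_mean = size[:, None] * profile[None, :]
                counts = _draw_counts(rng, cell_mean, config)
                for j in range(counts.shape[0]):
                    cid = f"{row.sample_id}_c{cell_no:05d}"
                    cell_no += 1
                    sample_cells.append(counts[j])
                    cell_rows.append((cid, row.sample_id, row.study_id, ct.name))
                    true_labels[cid] = ct.name
                    if is_abn:
                        abnormal.add(cid)
        blocks.append(np.vstack(sample_cells))
    dense = np.vstack(blocks)  # cells x genes
    counts = sp.csr_matrix(dense.T.astype(np.int64))
    cell_table = pd.DataFrame(
        cell_rows, columns=["cell_id", "sample_id", "study_id", "label"]
    )
    return counts, cell_table, true_labels, abnormal


def _sample_plan(config: CohortConfig, rng: np.random.Generator,
                 study_ids: Sequence[str], samples_per_study: int,
                 study_index: Sequence[int]) -> pd.DataFrame:
    rows = []
    for sid, s_idx in zip(study_ids, study_index):
        for k in range(samples_per_study):
            if config.ages is not None:
                age = float(rng.choice(np.asarray(config.ages)))
            else:
                age = float(rng.uniform(*config.age_range))
            sex = str(rng.choice(["F", "M"]))
            rows.append((f"{sid}_S{k:02d}", sid, s_idx, age, sex))
    return pd.DataFrame(
        rows, columns=["sample_id", "study_id", "study_index", "age_years", "sex"]
    )


def generate_reference(config: CohortConfig) -> Tuple[CellDataset, TruthBundle]:
    """Generate the multi-study reference cohort. Deterministic in config.seed."""
    config.validate()
    struct = _build_structure(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    study_ids = [f"ST{i:02d}" for i in range(config.n_studies)]
    plan = _sample_plan(config, rng, study_ids, config.samples_per_study,
                        list(range(config.n_studies)))
    counts, cell_table, labels, _ = _generate_cells(config, struct, plan, rng)
    ds = _assemble(config, struct, counts, cell_table, plan)
    truth = TruthBundle(
        sample_ages=dict(zip(plan["sample_id"], plan["age_years"])),
        trend_cell_types={ct.name: ct.proportion_age_slope for ct in config.cell_types},
        age_genes={
            (ct.name, struct.gene_ids[g]): struct.age_slopes[ct.name][g]
            for ct in config.cell_types
            for g in np.nonzero(struct.age_slopes[ct.name])[0]
        },
        abnormal_cells=set(),
        true_labels=labels,
        marker_genes={
            ct.name: tuple(struct.gene_ids[list(ct.marker_genes)])
            for ct in config.cell_types
        },
    )
    return ds, truth


def generate_query(reference_config: CohortConfig, n_samples: int,
                   abnormal_fraction: float = 0.0,
                   shift_magnitude: float = 0.0,
                   shifted_cell_type: Optional[str] = None,
                   n_shift_genes: int = 50,
                   seed: int = 0) -> Tuple[CellDataset, TruthBundle]:
    """Generate a query cohort from the reference generative model.

    A fraction of ``shifted_cell_type`` cells is displaced in log-mean
    space along a fixed sparse sign pattern over ``n_shift_genes`` genes
    drawn from the above-median-expression pool; each selected gene's
    log mean moves by ``+/- shift_magnitude`` (natural-log units).
    Deterministic given (config, seed).
    """
    reference_config.validate()
    names = [ct.name for ct in reference_config.cell_types]
    if abnormal_fraction and shifted_cell_type not in names:
        raise ConfigurationError(
            f"generate_query.shifted_cell_type: unknown cell type "
            f"{shifted_cell_type!r}; expected one of {names}"
        )
    if not 0.0 <= abnormal_fraction < 1.0:
        raise ConfigurationError(
            "generate_query.abnormal_fraction: must be in [0, 1)"
        )
    struct = _build_structure(reference_config)
    rng = np.random.default_rng(
        np.random.SeedSequence([reference_config.seed, 303, seed])
    )
    # query samples form their own study with a fresh batch factor
    batch = rng.normal(0.0, reference_config.batch_sd,
                       size=(1, reference_config.n_genes))
    struct = replace(struct, batch_log=batch)
    plan = _sample_plan(reference_config, rng, ["QRY"], n_samples, [0])

    shift = None
    shift_genes: Dict[str, float] = {}
    if abnormal_fraction > 0.0:
        expressed = np.nonzero(
            struct.base_log_rate >= np.median(struct.base_log_rate)
        )[0]
        pick = rng.choice(expressed, size=min(n_shift_genes, len(expressed)),
                          replace=False)
        direction = np.zeros(reference_config.n_genes)
        direction[pick] = rng.choice([-1.0, 1.0], size=len(pick))
        delta = shift_magnitude * direction
        shift = {"cell_type": shifted_cell_type, "fraction": abnormal_fraction,
                 "delta": delta}
        shift_genes = {struct.gene_ids[g]: float(delta[g]) for g in pick}

    counts, cell_table, labels, abnormal = _generate_cells(
        reference_config, struct, plan, rng, shift=shift
    )
    ds = _assemble(reference_config, struct, counts, cell_table, plan)
    truth = TruthBundle(
        sample_ages=dict(zip(plan["sample_id"], plan["age_years"])),
        trend_cell_types={ct.name: ct.proportion_age_slope
                          for ct in reference_config.cell_types},
        age_genes={},
        abnormal_cells=abnormal,
        true_labels=labels,
        marker_genes={
            ct.name: tuple(struct.gene_ids[list(ct.marker_genes)])
            for ct in reference_config.cell_types
        },
        shift_genes=shift_genes,
    )
    return ds, truth


def _assemble(config: CohortConfig, struct: _Structure, counts, cell_table,
              plan: pd.DataFrame) -> CellDataset:
    gene_table = pd.DataFrame({
        "gene_id": struct.gene_ids,
        "symbol": struct.symbols.astype(str),
    })
    gene_table["mito"] = gene_table["symbol"].str.startswith("MT-")
    gene_table["ribo"] = gene_table["symbol"].str.startswith(("RPL", "RPS"))
    sample_table = plan[["sample_id", "study_id", "age_years", "sex"]].copy()
    sample_table["sorted"] = False
    return CellDataset(counts, cell_table, gene_table, sample_table)
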