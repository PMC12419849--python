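"""Synthetic multi-tissue methylation data with known ground truth.

The generator emulates the structure of a multi-tissue methylation-array
compendium on the M-value scale:

* strong tissue-identity CpGs (per-tissue baseline offsets),
* a minority of CpGs with linear age trends in their logits — some shared
  across tissues, some specific to one tissue,
* deliberately unbalanced tissue sample counts and age ranges,
* additive Gaussian noise, sporadic missingness,
* optional technical-replicate pairs and serial-passage series.

For sample ``i`` and CpG ``j``::

    M_ij = mu_j + delta_{j, tissue(i)} + b_j * age_i * [j in scope(i)] + eps_ij

with ``eps ~ Normal(0, noise_sd^2)``.  Everything is determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .types import BETA_CLIP, IslandClockError, MethylationMatrix

__all__ = ["SimulationTruth", "simulate_dataset", "simulate_replicates", "simulate_passage_series"]


@dataclass
class SimulationTruth:
    """Parameters and (after generation) planted ground truth of a dataset.

    The defaults describe a desk-scale mirror of a tissue-unbalanced
    compendium: 2,000 CpGs of which 50 carry a shared age trend, 30 per
    tissue carry a tissue-specific trend and 200 mark tissue identity;
    four tissues of sizes 120/80/50/30 with different age ranges.
    """

    n_cpgs: int = 2000
    n_shared_age_cpgs: int = 50
    n_specific_age_cpgs_per_tissue: int = 30
    n_identity_cpgs: int = 200
    tissue_sizes: dict[str, int] = field(
        default_factory=lambda: {"cartilage": 120, "bone": 80, "muscle": 50, "tendon": 30}
    )
    age_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "cartilage": (30.0, 90.0),
            "bone": (40.0, 85.0),
            "muscle": (20.0, 75.0),
            "tendon": (20.0, 60.0),
        }
    )
    #: per-CpG age slope magnitudes are drawn uniformly from this range (M-units/year)
    slope_range: tuple[float, float] = (0.02, 0.05)
    #: SD of per-tissue baseline offsets at identity CpGs (M-units)
    identity_offset_sd: float = 2.0
    noise_sd: float = 0.3
    missing_rate: float = 0.0
    scale: str = "m"
    seed: int = 0
    dataset_id: str = "sim"

    # populated by simulate_dataset
    age_cpg_slopes: dict[str, float] = field(default_factory=dict)
    age_cpg_scope: dict[str, str] = field(default_factory=dict)  # "shared" or a tissue name
    identity_cpg_ids: list[str] = field(default_factory=list)
    # per-CpG baselines and tissue offsets, kept so derived generators
    # (passage series) share the same methylome; excluded from to_dict
    baseline_m: np.ndarray | None = field(default=None, repr=False, compare=False)
    tissue_offsets: np.ndarray | None = field(default=None, repr=False, compare=False)

    def validate(self) -> None:
        planted = (
            self.n_shared_age_cpgs
            + self.n_specific_age_cpgs_per_tissue * len(self.tissue_sizes)
            + self.n_identity_cpgs
        )
        if planted > self.n_cpgs:
            raise IslandClockError(
                f"planted CpG sets ({planted}) exceed the CpG universe ({self.n_cpgs})"
            )
        if len(self.tissue_sizes) < 2:
            raise IslandClockError("at least two tissues are required")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise IslandClockError("missing_rate must lie in [0, 1]")
        if self.noise_sd < 0:
            raise IslandClockError("noise_sd must be non-negative")
        if set(self.age_ranges) != set(self.tissue_sizes):
            raise IslandClockError("age_ranges and tissue_sizes must cover the same tissues")

    @property
    def planted_age_cpgs(self) -> list[str]:
        """All CpG ids carrying an age trend (shared and tissue-specific)."""
        return sorted(self.age_cpg_slopes)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("baseline_m", None)
        d.pop("tissue_offsets", None)
        d["age_ranges"] = {k: list(v) for k, v in self.age_ranges.items()}
        d["slope_range"] = list(self.slope_range)
        return d


def _m_to_beta(m: np.ndarray) -> np.ndarray:
    beta = 1.0 / (1.0 + np.power(2.0, -m))
    return np.clip(beta, BETA_CLIP, 1.0 - BETA_CLIP)


def simulate_dataset(truth: SimulationTruth) -> tuple[MethylationMatrix, pd.DataFrame, SimulationTruth]:
    """Generate a multi-tissue dataset; returns (matrix, sheet, completed truth)."""
    truth.validate()
    rng = np.random.default_rng(truth.seed)
    tissues = list(truth.tissue_sizes)
    n_cpgs = truth.n_cpgs
    cpg_ids = [f"cg{j:06d}" for j in range(n_cpgs)]

    # planted CpG sets are disjoint by construction
    order = rng.permutation(n_cpgs)
    k = 0
    shared = order[k : k + truth.n_shared_age_cpgs]
    k += truth.n_shared_age_cpgs
    specific: dict[str, np.ndarray] = {}
    for t in tissues:
        specific[t] = order[k : k + truth.n_specific_age_cpgs_per_tissue]
        k += truth.n_specific_age_cpgs_per_tissue
    identity = order[k : k + truth.n_identity_cpgs]

    mu = rng.uniform(-3.0, 3.0, size=n_cpgs)
    lo, hi = truth.slope_range
    slopes = np.zeros(n_cpgs)
    scope: dict[str, str] = {}
    for idx in shared:
        slopes[idx] = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
        scope[cpg_ids[idx]] = "shared"
    for t in tissues:
        for idx in specific[t]:
            slopes[idx] = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
            scope[cpg_ids[idx]] = t
    offsets = np.zeros((len(tissues), n_cpgs))
    offsets[:, identity] = rng.normal(0.0, truth.identity_offset_sd, size=(len(tissues), len(identity)))

    rows, sample_ids, ages, tissue_col = [], [], [], []
    for ti, t in enumerate(tissues):
        n_t = truth.tissue_sizes[t]
        a_lo, a_hi = truth.age_ranges[t]
        t_ages = rng.uniform(a_lo, a_hi, size=n_t)
        in_scope = np.zeros(n_cpgs, dtype=bool)
        in_scope[shared] = True
        in_scope[specific[t]] = True
        signal = mu[None, :] + offsets[ti][None, :] + np.where(in_scope, slopes, 0.0)[None, :] * t_ages[:, None]
        noise = rng.normal(0.0, truth.noise_sd, size=signal.shape) if truth.noise_sd > 0 else 0.0
        rows.append(signal + noise)
        for si in range(n_t):
            sample_ids.append(f"{t}_{si:03d}")
        ages.extend(t_ages)
        tissue_col.extend([t] * n_t)

    values = np.vstack(rows)
    if truth.missing_rate > 0:
        mask = rng.random(values.shape) < truth.missing_rate
        values = np.where(mask, np.nan, values)

    truth.age_cpg_slopes = {cpg_ids[i]: float(slopes[i]) for i in np.sort(np.concatenate([shared] + list(specific.values())))}
    truth.age_cpg_scope = {c: scope[c] for c in truth.age_cpg_slopes}
    truth.identity_cpg_ids = [cpg_ids[i] for i in np.sort(identity)]
    truth.baseline_m = mu
    truth.tissue_offsets = offsets

    if truth.scale == "beta":
        values = np.where(np.isnan(values), np.nan, _m_to_beta(values))
    matrix = MethylationMatrix(values, sample_ids, cpg_ids, truth.scale)
    sheet = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "age": np.asarray(ages),
            "tissue": tissue_col,
            "dataset": truth.dataset_id,
        }
    )
    return matrix, sheet, truth


def simulate_replicates(
    matrix: MethylationMatrix,
    sheet: pd.DataFrame,
    tech_sd: float,
    seed: int = 0,
) -> tuple[MethylationMatrix, pd.DataFrame]:
    """Emit two technical copies of every sample with independent M-noise.

    Each input sample yields a pair ``<id>_repA`` / ``<id>_repB`` linked by
    ``replicate_group``; both copies receive independent
    ``Normal(0, tech_sd^2)`` noise, so within-pair differences have SD
    ``tech_sd * sqrt(2)``.
    """
    if tech_sd < 0:
        raise IslandClockError("tech_sd must be non-negative")
    if matrix.scale != "m":
        raise IslandClockError("replicate noise is added on the M scale; convert first")
    rng = np.random.default_rng(seed)
    base = matrix.values
    noise_a = rng.normal(0.0, tech_sd, size=base.shape) if tech_sd > 0 else 0.0
    noise_b = rng.normal(0.0, tech_sd, size=base.shape) if tech_sd > 0 else 0.0
    values = np.vstack([base + noise_a, base + noise_b])
    ids_a = [f"{s}_repA" for s in matrix.sample_ids]
    ids_b = [f"{s}_repB" for s in matrix.sample_ids]
    rep_matrix = MethylationMatrix(values, ids_a + ids_b, list(matrix.cpg_ids), "m")
    meta = sheet.set_index("sample_id").loc[matrix.sample_ids]
    half = pd.DataFrame(
        {
            "age": meta["age"].to_numpy(),
            "tissue": meta["tissue"].to_numpy(),
            "dataset": meta["dataset"].to_numpy(),
            "replicate_group": matrix.sample_ids,
        }
    )
    rep_sheet = pd.concat(
        [half.assign(sample_id=ids_a), half.assign(sample_id=ids_b)], ignore_index=True
    )
    cols = ["sample_id", "age", "tissue", "dataset", "replicate_group"]
    return rep_matrix, rep_sheet[cols]


def simulate_passage_series(
    n_donors: int,
    doublings_grid: np.ndarray,
    years_per_doubling: float,
    truth: SimulationTruth,
    seed: int = 0,
    tissue: str | None = None,
    donor_age_range: tuple[float, float] = (25.0, 45.0),
) -> tuple[MethylationMatrix, pd.DataFrame]:
    """Serial-passage series: methylation driven by culture-accelerated age.

    Each donor is sampled at every point of ``doublings_grid``; the
    methylation of a sample reflects an *effective* age equal to the donor's
    chronological age plus ``years_per_doubling * doublings``, generated
    through the same planted-CpG model as :func:`simulate_dataset` (the
    ``truth`` argument must already carry planted slopes, i.e. come from a
    prior ``simulate_dataset`` call with the same seed).  The sheet records
    the chronological age and the ``population_doublings`` count.
    """
    doublings_grid = np.asarray(doublings_grid, dtype=float)
    if np.any(np.diff(doublings_grid) <= 0) or np.any(doublings_grid < 0):
        raise IslandClockError("doublings_grid must be non-negative and increasing")
    if not truth.age_cpg_slopes or truth.baseline_m is None:
        raise IslandClockError("truth carries no planted methylome; run simulate_dataset first")
    tissues = list(truth.tissue_sizes)
    tissue = tissue or tissues[0]
    if tissue not in tissues:
        raise IslandClockError(f"unknown tissue {tissue!r}")

    mu = truth.baseline_m
    offsets = truth.tissue_offsets
    cpg_ids = [f"cg{j:06d}" for j in range(truth.n_cpgs)]
    ti = tissues.index(tissue)

    slopes = np.zeros(truth.n_cpgs)
    index = {c: j for j, c in enumerate(cpg_ids)}
    in_scope = np.zeros(truth.n_cpgs, dtype=bool)
    for c, b in truth.age_cpg_slopes.items():
        j = index[c]
        slopes[j] = b
        if truth.age_cpg_scope[c] in ("shared", tissue):
            in_scope[j] = True

    rng = np.random.default_rng(seed)
    donor_ages = rng.uniform(*donor_age_range, size=n_donors)
    rows, sample_ids, ages, dbl = [], [], [], []
    for d in range(n_donors):
        for pd_count in doublings_grid:
            eff_age = donor_ages[d] + years_per_doubling * pd_count
            signal = mu + offsets[ti] + np.where(in_scope, slopes, 0.0) * eff_age
            noise = rng.normal(0.0, truth.noise_sd, size=truth.n_cpgs) if truth.noise_sd > 0 else 0.0
            rows.append(signal + noise)
            sample_ids.append(f"donor{d:02d}_pd{pd_count:05.1f}")
            ages.append(donor_ages[d])
            dbl.append(pd_count)
    matrix = MethylationMatrix(np.vstack(rows), sample_ids, cpg_ids, "m")
    sheet = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "age": ages,
            "tissue": tissue,
            "dataset": f"{truth.dataset_id}_passage",
            "population_doublings": dbl,
        }
    )
    return matrix, sheet
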