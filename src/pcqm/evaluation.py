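"""Monte Carlo evaluation of the PCQM estimator families.

One *scenario* fixes a population (a generated or imported point
pattern) and crosses sample sizes x orders x estimator families; each
cell is replicated I times (default 1,000) by redrawing the survey's
sample points against the fixed population. Accuracy per cell is
summarised by the relative root mean square error

    RRMSE = sqrt( sum (rho_hat - rho)^2 / (I rho^2) )

and the signed relative bias

    RBIAS = (mean(rho_hat) - rho) / rho,

negative RBIAS meaning underestimation of the true density. Rank-based
tests (Wilcoxon rank-sum between families, Kruskal-Wallis plus Dunn/Holm
post hoc across orders) operate on the raw per-replicate estimates.

Replicate r of a cell at sample size N derives its RNG stream from
(master seed, scenario id, N, r), so every estimate is reproducible
bit-for-bit and streams are independent across cells.
"""

from __future__ import annotations

import dataclasses
import itertools
import zlib
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .estimators import ESTIMATOR_FAMILIES, density_from_sum_sq
from .exceptions import (
    InvalidSpecError,
    InvalidTrueDensityError,
    ResultsCSVError,
    SamplingFailureError,
    VacantQuadrantError,
)
from .patterns import PatternSpec, PointPattern, generate
from .sampler import _order_distance_matrix, draw_sample_points

__all__ = [
    "ScenarioConfig",
    "ScenarioResult",
    "OrderComparison",
    "rrmse",
    "rbias",
    "run_scenario",
    "compare_estimator_families",
    "compare_orders",
    "write_results_csv",
    "read_results_csv",
    "write_metrics_csv",
]

#: Sample-size grid of the original simulation study.
DEFAULT_SAMPLE_SIZES = (10, 15, 20, 25, 30, 50, 100)

RAW_COLUMNS = [
    "scenario_id",
    "pattern_kind",
    "true_density",
    "samples",
    "pcqm_eqn",
    "pcqm_type",
    "replicate",
    "density_ha",
    "status",
]

METRICS_COLUMNS = [
    "scenario_id",
    "pattern_kind",
    "true_density",
    "samples",
    "pcqm_eqn",
    "pcqm_type",
    "rrmse",
    "rbias",
    "n_replicates",
    "n_failed",
]


@dataclasses.dataclass(frozen=True)
class ScenarioConfig:
    """One Monte Carlo cell grid: a population crossed with survey settings.

    ``pattern`` may be a :class:`PatternSpec` or an already-realised
    :class:`PointPattern` (e.g. an imported stem map, which is naturally
    fixed). For a spec, ``regenerate`` controls whether the population
    is re-established every replicate (``"replicate"``, the default —
    each simulation run builds a fresh stand from the same scenario
    parameters, so the estimate distribution is unconditional) or
    realised once and surveyed repeatedly (``"scenario"`` — every
    replicate sees the same stand, so cell summaries are conditional on
    that one realization and carry its idiosyncratic offset). Exact-n
    generators give every realization the identical true density, so
    RRMSE/RBIAS reference the same rho either way.
    """

    scenario_id: str
    pattern: PatternSpec | PointPattern
    sample_sizes: Sequence[int] = DEFAULT_SAMPLE_SIZES
    orders: Sequence[int] = (1, 2, 3)
    estimators: Sequence[str] = ESTIMATOR_FAMILIES
    replicates: int = 1000
    boundary_fraction: float = 0.10
    vacancy_policy: str = "error"
    regenerate: str = "replicate"
    seed: int = 0

    def __post_init__(self):
        if self.regenerate not in ("replicate", "scenario"):
            raise InvalidSpecError(
                f"regenerate must be 'replicate' or 'scenario', "
                f"got {self.regenerate!r}"
            )
        if self.replicates < 1:
            raise InvalidSpecError(f"replicates must be >= 1, got {self.replicates}")
        if any(n < 1 for n in self.sample_sizes):
            raise InvalidSpecError(f"sample sizes must be >= 1: {self.sample_sizes}")
        if any(g < 1 for g in self.orders):
            raise InvalidSpecError(f"orders must be >= 1: {self.orders}")
        bad = [e for e in self.estimators if e not in ESTIMATOR_FAMILIES]
        if bad:
            raise InvalidSpecError(f"unknown estimator families: {bad}")


@dataclasses.dataclass(frozen=True, eq=False)
class ScenarioResult:
    """Output of :func:`run_scenario`: the realised population, the
    per-cell metrics table and the raw per-replicate estimates."""

    config: ScenarioConfig
    pattern: PointPattern
    metrics: pd.DataFrame
    raw: pd.DataFrame


def rrmse(estimates, true_density: float) -> float:
    """Relative root mean square error against the true density."""
    est = np.asarray(estimates, dtype=float)
    if est.size < 1:
        raise InvalidSpecError("rrmse needs at least one estimate")
    if not true_density > 0:
        raise InvalidTrueDensityError(
            f"true density must be > 0, got {true_density}"
        )
    return float(np.sqrt(np.mean((est - true_density) ** 2)) / true_density)


def rbias(estimates, true_density: float) -> float:
    """Signed relative bias; negative values mean underestimation."""
    est = np.asarray(estimates, dtype=float)
    if est.size < 1:
        raise InvalidSpecError("rbias needs at least one estimate")
    if not true_density > 0:
        raise InvalidTrueDensityError(
            f"true density must be > 0, got {true_density}"
        )
    return float((est.mean() - true_density) / true_density)


def _scenario_key(scenario_id: str) -> int:
    """Stable 32-bit key so distinct scenario ids get distinct streams."""
    return zlib.crc32(scenario_id.encode("utf-8"))


def replicate_seed(
    master_seed: int, scenario_id: str, n_points: int, replicate: int
) -> np.random.SeedSequence:
    """Deterministic per-replicate RNG stream for one cell."""
    return np.random.SeedSequence(
        entropy=(int(master_seed), _scenario_key(scenario_id), int(n_points), int(replicate))
    )


def _realise_pattern(config: ScenarioConfig) -> tuple[PointPattern, str]:
    if isinstance(config.pattern, PointPattern):
        return config.pattern, "imported"
    spec = config.pattern
    if spec.seed is None:
        spec = dataclasses.replace(
            spec,
            seed=np.random.SeedSequence(
                entropy=(int(config.seed), _scenario_key(config.scenario_id))
            ),
        )
    return generate(spec), spec.kind


def run_scenario(config: ScenarioConfig) -> ScenarioResult:
    """Run the full replicate grid of one scenario.

    Each replicate re-establishes the population from the scenario's
    pattern spec (default; see :class:`ScenarioConfig`), redraws sample
    points, measures every requested order at those points in a single
    pass (orders share the survey, as they would in the field), and
    applies every requested estimator family. A replicate whose survey
    fails (vacant quadrant on a sparse pattern, or redraw budget
    exhausted) is recorded with a failure status and a NaN density —
    never imputed — and the cell metrics are computed over the
    successful replicates with ``n_failed`` flagging the cell.

    ``ScenarioResult.pattern`` is a representative realization (the one
    surveyed in ``"scenario"`` mode), e.g. for reporting the
    Clark–Evans index of the stand structure.
    """
    pattern, kind = _realise_pattern(config)
    rho = pattern.true_density
    per_replicate = (
        config.regenerate == "replicate"
        and isinstance(config.pattern, PatternSpec)
    )
    orders = sorted(set(int(g) for g in config.orders))
    gmax = orders[-1]
    families = list(config.estimators)
    i_reps = config.replicates

    raw_rows = []
    metric_rows = []
    for n_points in config.sample_sizes:
        values = {
            (g, fam): np.full(i_reps, np.nan) for g in orders for fam in families
        }
        status = np.array(["ok"] * i_reps, dtype=object)
        for rep in range(i_reps):
            ss = replicate_seed(config.seed, config.scenario_id, n_points, rep)
            if per_replicate:
                pat_ss, samp_ss = ss.spawn(2)
                rep_pattern = generate(
                    dataclasses.replace(config.pattern, seed=pat_ss)
                )
                rng = np.random.default_rng(samp_ss)
            else:
                rep_pattern = pattern
                rng = np.random.default_rng(ss)
            try:
                sum_sq = _measure_sum_sq(
                    rep_pattern, n_points, orders, gmax,
                    config.boundary_fraction, rng, config.vacancy_policy,
                )
            except (VacantQuadrantError, SamplingFailureError) as exc:
                status[rep] = f"failed: {type(exc).__name__}"
                continue
            for g in orders:
                for fam in families:
                    values[(g, fam)][rep] = density_from_sum_sq(
                        sum_sq[g], n_points, g, fam
                    )
        ok = status == "ok"
        for fam in families:
            for g in orders:
                v = values[(g, fam)]
                good = v[ok]
                metric_rows.append(
                    {
                        "scenario_id": config.scenario_id,
                        "pattern_kind": kind,
                        "true_density": rho,
                        "samples": n_points,
                        "pcqm_eqn": fam,
                        "pcqm_type": g,
                        "rrmse": rrmse(good, rho) if good.size else np.nan,
                        "rbias": rbias(good, rho) if good.size else np.nan,
                        "n_replicates": int(good.size),
                        "n_failed": int(i_reps - good.size),
                    }
                )
                raw_rows.append(
                    pd.DataFrame(
                        {
                            "scenario_id": config.scenario_id,
                            "pattern_kind": kind,
                            "true_density": rho,
                            "samples": n_points,
                            "pcqm_eqn": fam,
                            "pcqm_type": g,
                            "replicate": np.arange(i_reps),
                            "density_ha": v,
                            "status": status,
                        }
                    )
                )
    metrics = pd.DataFrame(metric_rows, columns=METRICS_COLUMNS)
    raw = pd.concat(raw_rows, ignore_index=True)[RAW_COLUMNS]
    return ScenarioResult(config=config, pattern=pattern, metrics=metrics, raw=raw)


def _measure_sum_sq(
    pattern: PointPattern,
    n_points: int,
    orders: list[int],
    gmax: int,
    boundary_fraction: float,
    rng: np.random.Generator,
    vacancy_policy: str,
) -> dict[int, float]:
    """One replicate's sum of squared distances for every order.

    Inlines the collect loop of :mod:`pcqm.sampler` on the shared
    distance matrix so a replicate measures its trees once regardless of
    how many orders and families consume it.
    """
    from .sampler import _MAX_DRAWS_PER_POINT  # shared budget constant

    pts = draw_sample_points(pattern, n_points, boundary_fraction, rng)
    mat = _order_distance_matrix(pattern.points, pts, gmax)
    draws = n_points
    max_draws = _MAX_DRAWS_PER_POINT * n_points
    while True:
        vacant = np.isinf(mat[:, :, gmax - 1]).any(axis=1)
        coincident = (mat[:, :, 0] == 0.0).any(axis=1)
        if vacancy_policy == "error" and vacant.any():
            i = int(np.flatnonzero(vacant)[0])
            q = int(np.flatnonzero(np.isinf(mat[i, :, gmax - 1]))[0])
            raise VacantQuadrantError(
                f"quadrant {q + 1} at sample point {tuple(pts[i])} holds "
                f"fewer than {gmax} trees",
                point_index=i,
                quadrant=q,
            )
        redo = vacant | coincident
        if not redo.any():
            break
        k = int(redo.sum())
        if draws + k > max_draws:
            raise SamplingFailureError(
                f"redraw budget of {max_draws} draws exhausted with only "
                f"{n_points - k} of {n_points} valid sample points",
                n_valid=n_points - k,
            )
        fresh = draw_sample_points(pattern, k, boundary_fraction, rng)
        draws += k
        idx = np.flatnonzero(redo)
        pts[idx] = fresh
        mat[idx] = _order_distance_matrix(pattern.points, fresh, gmax)
    return {g: float(np.sum(mat[:, :, g - 1] ** 2)) for g in orders}


def compare_estimator_families(raw_a, raw_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test between two sets of estimates.

    Returns (statistic, p-value). Used to ask whether the corrected and
    published families produce systematically different densities on the
    same replicate grid.
    """
    a = np.asarray(raw_a, dtype=float)
    b = np.asarray(raw_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidSpecError("both estimate sets must be nonempty")
    res = stats.ranksums(a, b)
    return float(res.statistic), float(res.pvalue)


@dataclasses.dataclass(frozen=True, eq=False)
class OrderComparison:
    """Kruskal-Wallis omnibus result plus the pairwise Dunn post hoc."""

    statistic: float
    pvalue: float
    posthoc: pd.DataFrame


def compare_orders(raw_1, raw_2, raw_3, adjust: str = "holm") -> OrderComparison:
    """Compare PCQM1/2/3 estimate distributions.

    Omnibus Kruskal-Wallis across the three groups, then Dunn's pairwise
    rank comparison (normal approximation on mean pooled ranks, with tie
    correction). ``adjust`` is 'holm' (default) or 'none' for the
    unadjusted pairwise p-values.
    """
    groups = [np.asarray(g, dtype=float) for g in (raw_1, raw_2, raw_3)]
    if any(g.size == 0 for g in groups):
        raise InvalidSpecError("all three estimate sets must be nonempty")
    if adjust not in ("holm", "none"):
        raise InvalidSpecError(f"adjust must be 'holm' or 'none', got {adjust!r}")
    stat, p = stats.kruskal(*groups)
    posthoc = _dunn_posthoc(groups, labels=["PCQM1", "PCQM2", "PCQM3"], adjust=adjust)
    return OrderComparison(statistic=float(stat), pvalue=float(p), posthoc=posthoc)


def _dunn_posthoc(
    groups: list[np.ndarray], labels: list[str], adjust: str = "holm"
) -> pd.DataFrame:
    """Dunn's z-test on mean pooled ranks for every pair of groups."""
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    sizes = [g.size for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [
        ranks[bounds[i]: bounds[i + 1]].mean() for i in range(len(groups))
    ]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_base = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))

    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "z": float(z),
                "pvalue": float(2.0 * stats.norm.sf(abs(z))),
            }
        )
    table = pd.DataFrame(rows)
    if adjust == "holm":
        table["pvalue_adjusted"] = multipletests(table["pvalue"], method="holm")[1]
    else:
        table["pvalue_adjusted"] = table["pvalue"]
    return table


def write_results_csv(raw: pd.DataFrame, path) -> None:
    """Write the long-format per-replicate table, 10 significant digits."""
    missing = [c for c in RAW_COLUMNS if c not in raw.columns]
    if missing:
        raise ResultsCSVError(f"raw table missing column(s) {', '.join(missing)}")
    raw[RAW_COLUMNS].to_csv(path, index=False, float_format="%.10g")


def read_results_csv(path) -> pd.DataFrame:
    """Read a per-replicate results CSV back; validates schema and types."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ResultsCSVError(f"{path}: file is empty") from None
    missing = [c for c in RAW_COLUMNS if c not in df.columns]
    if missing:
        raise ResultsCSVError(
            f"{path}: missing column(s) {', '.join(missing)}", row=1
        )
    for col in ("true_density", "samples", "pcqm_type", "replicate", "density_ha"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ResultsCSVError(
                f"{path}: non-numeric value in column {col!r} at line {i + 2}",
                row=i + 2,
            )
        df[col] = coerced
    return df


def write_metrics_csv(metrics: pd.DataFrame, path) -> None:
    """Write the per-cell RRMSE/RBIAS summary table."""
    metrics[METRICS_COLUMNS].to_csv(path, index=False, float_format="%.10g")
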