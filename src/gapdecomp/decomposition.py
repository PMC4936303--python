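"""Aggregate and detailed decomposition of the group gap in a binary outcome.

The aggregate decomposition splits the nonpoor-minus-poor gap in weighted
outcome means into an explained (endowment) portion — the change in average
predicted probability when the benchmark coefficient vector is applied to the
two groups' covariate distributions — and an unexplained remainder.

The detailed decomposition attributes the explained portion to covariate
blocks by one-to-one rank matching of observations on predicted probability,
then switching each matched pair's block values from the poor record's to the
counterpart's, one block at a time in a given order.  Because the ordering is
arbitrary, replications redraw both the matched subsample and a uniformly
random block ordering, and results are reported as means across replications.

Conventions (documented package decisions):

* The larger group — whichever it is — is subsampled without replacement to
  the smaller group's size before matching.
* Pairs are formed ignoring weights; contribution means use the poor
  record's normalized weight.
* Ties in predicted-probability ranks are broken by a seeded shuffle.
* Contribution standard errors are across-replication standard deviations of
  the per-replication contributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import AssemblyError, ValidationError
from .estimation import LogitFit, predict_prob, significance_stars
from .survey import DesignMatrix, INTERCEPT

__all__ = [
    "AggregateDecomposition",
    "MatchedSample",
    "DetailedDecomposition",
    "DecompositionReport",
    "aggregate_decomposition",
    "match_samples",
    "detailed_decomposition_single",
    "replicate_detailed_decomposition",
    "decomposition_report",
]


def _wmean(v: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(w * v) / np.sum(w))


@dataclass
class AggregateDecomposition:
    """Gap, explained and unexplained portions for one benchmark."""

    benchmark: str
    mean_nonpoor: float
    mean_poor: float
    gap: float
    explained: float
    unexplained: float

    @property
    def explained_pct(self) -> float:
        return 100.0 * self.explained / self.gap

    @property
    def unexplained_pct(self) -> float:
        return 100.0 * self.unexplained / self.gap


def aggregate_decomposition(
    fit_benchmark: LogitFit,
    dm_poor: DesignMatrix,
    dm_nonpoor: DesignMatrix,
    check_tol: float = 1e-6,
    fit_poor: LogitFit | None = None,
    fit_nonpoor: LogitFit | None = None,
) -> AggregateDecomposition:
    """Two-fold decomposition of the weighted outcome-mean gap.

    ``explained`` is the weighted mean of predicted probabilities under the
    benchmark coefficients over nonpoor rows minus that over poor rows;
    ``unexplained`` is the residual, which makes the telescoping identity
    ``explained + unexplained == gap`` exact.  When the matching group's own
    fit is supplied, the residual is verified against the directly computed
    coefficient-difference bracket (its own average prediction must
    reproduce its observed mean, which holds at the pseudo-ML optimum).
    """
    fit_benchmark.require_converged()
    mean_p = _wmean(dm_poor.y, dm_poor.weights)
    mean_np = _wmean(dm_nonpoor.y, dm_nonpoor.weights)
    gap = mean_np - mean_p

    p_poor = predict_prob(fit_benchmark, dm_poor)
    p_nonpoor = predict_prob(fit_benchmark, dm_nonpoor)
    explained = _wmean(p_nonpoor, dm_nonpoor.weights) - _wmean(p_poor, dm_poor.weights)
    unexplained = gap - explained

    # direct second-bracket check against the group's own fit
    direct = None
    if fit_benchmark.benchmark == "nonpoor" and fit_poor is not None:
        fit_poor.require_converged()
        direct = _wmean(p_poor, dm_poor.weights) - _wmean(
            predict_prob(fit_poor, dm_poor), dm_poor.weights
        )
    elif fit_benchmark.benchmark == "poor" and fit_nonpoor is not None:
        fit_nonpoor.require_converged()
        direct = _wmean(predict_prob(fit_nonpoor, dm_nonpoor), dm_nonpoor.weights) - _wmean(
            p_nonpoor, dm_nonpoor.weights
        )
    if direct is not None and abs(direct - unexplained) > check_tol:
        raise AssemblyError(
            f"second-bracket check failed: direct {direct:.3e} vs residual "
            f"{unexplained:.3e} (benchmark {fit_benchmark.benchmark!r})"
        )

    return AggregateDecomposition(
        benchmark=fit_benchmark.benchmark,
        mean_nonpoor=mean_np,
        mean_poor=mean_p,
        gap=gap,
        explained=explained,
        unexplained=unexplained,
    )


@dataclass
class MatchedSample:
    """One-to-one rank matching of poor records to counterpart records."""

    poor_pos: np.ndarray  # positions into dm_poor rows, rank-ordered
    counterpart_pos: np.ndarray  # positions into dm_nonpoor rows, aligned
    subsample_seed: int
    ranking_benchmark: str

    @property
    def n_pairs(self) -> int:
        return self.poor_pos.size


def _ranked(p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Argsort by predicted probability, ties broken by a seeded shuffle."""
    tiebreak = rng.permutation(p.size)
    return np.lexsort((tiebreak, p))


def match_samples(
    dm_poor: DesignMatrix,
    dm_nonpoor: DesignMatrix,
    ranking_fit: LogitFit,
    seed: int,
) -> MatchedSample:
    """Subsample the larger group to the smaller size and pair by rank.

    Both sides are sorted ascending by ``ranking_fit`` predicted probability;
    pairs are formed by rank position.
    """
    ranking_fit.require_converged()
    if dm_poor.n_obs == 0 or dm_nonpoor.n_obs == 0:
        raise ValidationError("both groups must be non-empty for matching")
    rng = np.random.default_rng(seed)

    n = min(dm_poor.n_obs, dm_nonpoor.n_obs)
    poor_pos = np.arange(dm_poor.n_obs)
    np_pos = np.arange(dm_nonpoor.n_obs)
    if dm_poor.n_obs > n:
        poor_pos = rng.choice(dm_poor.n_obs, size=n, replace=False)
    elif dm_nonpoor.n_obs > n:
        np_pos = rng.choice(dm_nonpoor.n_obs, size=n, replace=False)

    p_poor = predict_prob(ranking_fit, dm_poor.values[poor_pos])
    p_np = predict_prob(ranking_fit, dm_nonpoor.values[np_pos])
    poor_pos = poor_pos[_ranked(p_poor, rng)]
    np_pos = np_pos[_ranked(p_np, rng)]
    return MatchedSample(
        poor_pos=poor_pos,
        counterpart_pos=np_pos,
        subsample_seed=seed,
        ranking_benchmark=ranking_fit.benchmark,
    )


def detailed_decomposition_single(
    match: MatchedSample,
    dm_poor: DesignMatrix,
    dm_nonpoor: DesignMatrix,
    fit_benchmark: LogitFit,
    ordering: list[str],
) -> pd.Series:
    """Sequential per-block contributions on one matched sample.

    For the block at position k of ``ordering``, the contribution is the
    weighted mean over pairs of the predicted probability with counterpart
    values substituted for blocks at positions <= k (poor values elsewhere)
    minus the same with substitution only at positions < k.  The intercept is
    never switched.  Contributions telescope: they sum exactly to the
    matched-sample explained portion.  Returned indexed by block name in the
    design's block order.
    """
    fit_benchmark.require_converged()
    blocks = dm_poor.blocks
    if sorted(ordering) != sorted(blocks):
        raise ValidationError(
            f"ordering {ordering} is not a permutation of blocks {blocks}"
        )

    X = dm_poor.values[match.poor_pos].copy()
    X_cp = dm_nonpoor.values[match.counterpart_pos]
    w = dm_poor.weights[match.poor_pos]
    w = w / w.sum()

    prev = float(w @ predict_prob(fit_benchmark, X))
    contrib = {}
    for block in ordering:
        cols = dm_poor.block_columns(block)
        X[:, cols] = X_cp[:, cols]
        cur = float(w @ predict_prob(fit_benchmark, X))
        contrib[block] = cur - prev
        prev = cur
    return pd.Series([contrib[b] for b in blocks], index=blocks, dtype=float)


def matched_explained(
    match: MatchedSample,
    dm_poor: DesignMatrix,
    dm_nonpoor: DesignMatrix,
    fit_benchmark: LogitFit,
) -> float:
    """Explained portion on the matched sample (full switch, no ordering)."""
    w = dm_poor.weights[match.poor_pos]
    w = w / w.sum()
    p_cp = predict_prob(fit_benchmark, dm_nonpoor.values[match.counterpart_pos])
    p_poor = predict_prob(fit_benchmark, dm_poor.values[match.poor_pos])
    return float(w @ p_cp - w @ p_poor)


@dataclass
class DetailedDecomposition:
    """Per-block contributions averaged over matched-sample replications."""

    benchmark: str
    replications: int
    root_seed: int
    blocks: list[str]
    contribution_mean: pd.Series  # probability points, per block
    contribution_se: pd.Series  # across-replication std (ddof=1)
    percent_of_gap: pd.Series
    explained_detailed: float  # mean matched-sample explained portion
    explained_se: float
    gap: float
    draws: pd.DataFrame = field(repr=False, default=None)  # R x blocks

    def summary(self) -> pd.DataFrame:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(
                self.contribution_se.to_numpy() > 0,
                self.contribution_mean.to_numpy() / self.contribution_se.to_numpy(),
                np.inf,
            )
        from scipy.stats import norm

        p = 2.0 * norm.sf(np.abs(t))
        return pd.DataFrame(
            {
                "block": self.blocks,
                "contribution": self.contribution_mean.to_numpy(),
                "se": self.contribution_se.to_numpy(),
                "percent_of_gap": self.percent_of_gap.to_numpy(),
                "stars": [significance_stars(v) for v in p],
            }
        )


def replicate_detailed_decomposition(
    dm_poor: DesignMatrix,
    dm_nonpoor: DesignMatrix,
    fit_benchmark: LogitFit,
    ranking_fit: LogitFit,
    R: int = 100,
    root_seed: int = 0,
    orderings: list[list[str]] | None = None,
) -> DetailedDecomposition:
    """Detailed decomposition over R matched-sample/ordering replications.

    Child seeds for each replication's subsample draw and ordering shuffle are
    spawned deterministically from ``root_seed``.  ``orderings`` overrides the
    random block ordering (one list per replication) — used for tests.
    """
    if R < 1:
        raise ValidationError("R must be >= 1")
    blocks = dm_poor.blocks
    gap = _wmean(dm_nonpoor.y, dm_nonpoor.weights) - _wmean(dm_poor.y, dm_poor.weights)

    children = np.random.SeedSequence(root_seed).spawn(R)
    rows = []
    explained_draws = np.empty(R)
    for r in range(R):
        match_seed_seq, order_seq = children[r].spawn(2)
        match_seed = int(match_seed_seq.generate_state(1)[0])
        match = match_samples(dm_poor, dm_nonpoor, ranking_fit, match_seed)
        if orderings is not None:
            ordering = list(orderings[r])
        else:
            order_rng = np.random.default_rng(order_seq)
            ordering = [blocks[i] for i in order_rng.permutation(len(blocks))]
        contrib = detailed_decomposition_single(match, dm_poor, dm_nonpoor, fit_benchmark, ordering)
        rows.append(contrib)
        explained_draws[r] = contrib.sum()

    draws = pd.DataFrame(rows).reset_index(drop=True)
    mean = draws.mean(axis=0)
    se = draws.std(axis=0, ddof=1) if R > 1 else pd.Series(0.0, index=draws.columns)
    return DetailedDecomposition(
        benchmark=fit_benchmark.benchmark,
        replications=R,
        root_seed=root_seed,
        blocks=blocks,
        contribution_mean=mean,
        contribution_se=se,
        percent_of_gap=100.0 * mean / gap,
        explained_detailed=float(explained_draws.mean()),
        explained_se=float(explained_draws.std(ddof=1)) if R > 1 else 0.0,
        gap=gap,
        draws=draws,
    )


@dataclass
class DecompositionReport:
    """Aggregate + detailed results for every requested benchmark."""

    aggregate: dict[str, AggregateDecomposition]
    detailed: dict[str, DetailedDecomposition]

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for bench, det in self.detailed.items():
            f = det.summary()
            f.insert(0, "benchmark", bench)
            frames.append(f)
        for bench, agg in self.aggregate.items():
            frames.append(
                pd.DataFrame(
                    {
                        "benchmark": [bench, bench],
                        "block": ["total_explained", "total_unexplained"],
                        "contribution": [agg.explained, agg.unexplained],
                        "se": [np.nan, np.nan],
                        "percent_of_gap": [agg.explained_pct, agg.unexplained_pct],
                        "stars": ["", ""],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def to_dict(self) -> dict:
        out = {}
        for bench, agg in self.aggregate.items():
            det = self.detailed.get(bench)
            entry = {
                "mean_nonpoor": agg.mean_nonpoor,
                "mean_poor": agg.mean_poor,
                "gap": agg.gap,
                "explained": agg.explained,
                "unexplained": agg.unexplained,
                "explained_pct": agg.explained_pct,
                "unexplained_pct": agg.unexplained_pct,
            }
            if det is not None:
                entry["replications"] = det.replications
                entry["root_seed"] = det.root_seed
                entry["explained_detailed"] = det.explained_detailed
                entry["blocks"] = {
                    b: {
                        "contribution": float(det.contribution_mean[b]),
                        "se": float(det.contribution_se[b]),
                        "percent_of_gap": float(det.percent_of_gap[b]),
                    }
                    for b in det.blocks
                }
            out[bench] = entry
        return out


def decomposition_report(
    aggregates: dict[str, AggregateDecomposition],
    detailed: dict[str, DetailedDecomposition],
    tol: float = 1e-10,
) -> DecompositionReport:
    """Assemble and cross-check aggregate and detailed results.

    Raises :class:`AssemblyError` when benchmark labels disagree or when a
    detailed decomposition's per-replication contributions fail to telescope
    to its matched-sample explained portion.
    """
    for bench, det in detailed.items():
        if bench not in aggregates:
            raise AssemblyError(f"detailed benchmark {bench!r} has no aggregate counterpart")
        if det.benchmark != bench or aggregates[bench].benchmark != bench:
            raise AssemblyError(f"benchmark label mismatch for {bench!r}")
        if det.draws is not None:
            sums = det.draws.sum(axis=1).to_numpy()
            if det.draws.shape[0] and abs(sums.mean() - det.explained_detailed) > tol:
                raise AssemblyError(
                    "detailed contributions do not sum to the matched-sample explained portion"
                )
    return DecompositionReport(aggregate=dict(aggregates), detailed=dict(detailed))
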