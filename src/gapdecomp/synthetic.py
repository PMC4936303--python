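"""Synthetic survey micro-data with known group-specific outcome processes.

The generator mimics a stratified two-stage cluster design: strata contain
PSUs, PSUs contain households, and each household contributes one birth
record.  A latent household wealth score (stratum effect plus noise) drives
both the asset indicators — from which the observable wealth index is built
by principal components — and the covariate level probabilities.  Outcomes
are Bernoulli draws from a logistic model whose coefficient vector depends on
the household's wealth group, with an optional PSU-level random intercept.

Wealth-group labels are never written to the generated table; the poor /
nonpoor split used to pick the true coefficient vector is derived from the
asset index through the same weighted-quintile rule the analysis pipeline
applies, so the generating process and the estimation path agree.

All randomness flows from one root seed through named child streams, so any
stage can be replayed in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .errors import ConfigError, ValidationError
from .survey import (
    Block,
    MicroData,
    ModelSpec,
    POOR,
    assign_wealth_groups,
)

__all__ = [
    "CovariateLaw",
    "SyntheticConfig",
    "OracleDecomposition",
    "generate_population",
    "compute_asset_index",
    "oracle_expected_decomposition",
    "example_config",
]


@dataclass(frozen=True)
class CovariateLaw:
    """How one covariate block's level probabilities depend on latent wealth.

    Level probabilities are ``softmax(base_logits + wealth_slopes * wealth)``,
    which sums to one at every wealth score by construction.
    """

    name: str
    levels: tuple
    reference: object
    base_logits: tuple
    wealth_slopes: tuple
    kind: str = "categorical"
    partner: bool = False

    def __post_init__(self):
        if not (len(self.levels) == len(self.base_logits) == len(self.wealth_slopes)):
            raise ConfigError(
                f"law {self.name!r}: levels, base_logits and wealth_slopes must align"
            )
        if self.reference not in self.levels:
            raise ConfigError(f"law {self.name!r}: reference not among levels")
        if self.kind == "binary" and len(self.levels) != 2:
            raise ConfigError(f"binary law {self.name!r} must have 2 levels")

    def block(self) -> Block:
        return Block(
            name=self.name,
            kind=self.kind,
            levels=self.levels,
            reference=self.reference,
            partner=self.partner,
        )

    def probs(self, wealth: np.ndarray) -> np.ndarray:
        """(n, L) level-probability matrix at each wealth score."""
        logits = np.asarray(self.base_logits) + np.outer(wealth, np.asarray(self.wealth_slopes))
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        return p / p.sum(axis=1, keepdims=True)


@dataclass
class SyntheticConfig:
    """Full specification of the synthetic population."""

    n_strata: int
    psus_per_stratum: int
    households_per_psu: int
    asset_count: int
    true_beta_poor: np.ndarray  # log-odds, incl. intercept, design order
    true_beta_nonpoor: np.ndarray
    covariates: list[CovariateLaw]
    psu_effect_sd: float = 0.0
    weight_scheme: str = "uniform"  # "uniform" | "inverse-selection"
    seed: int = 0

    def __post_init__(self):
        self.true_beta_poor = np.asarray(self.true_beta_poor, dtype=float)
        self.true_beta_nonpoor = np.asarray(self.true_beta_nonpoor, dtype=float)
        for name, v in (
            ("n_strata", self.n_strata),
            ("psus_per_stratum", self.psus_per_stratum),
            ("households_per_psu", self.households_per_psu),
            ("asset_count", self.asset_count),
        ):
            if int(v) < 1:
                raise ConfigError(f"{name} must be a positive count (got {v})")
        if self.psu_effect_sd < 0:
            raise ConfigError("psu_effect_sd must be >= 0")
        if self.weight_scheme not in ("uniform", "inverse-selection"):
            raise ConfigError(f"unknown weight_scheme {self.weight_scheme!r}")
        if self.true_beta_poor.shape != self.true_beta_nonpoor.shape:
            raise ConfigError("true_beta_poor and true_beta_nonpoor must have identical length")
        k = 1 + sum(len(law.levels) - 1 for law in self.covariates)
        if self.true_beta_poor.size != k:
            raise ConfigError(
                f"beta length {self.true_beta_poor.size} does not conform to the "
                f"covariate design ({k} columns incl. intercept)"
            )

    @property
    def n_births(self) -> int:
        return self.n_strata * self.psus_per_stratum * self.households_per_psu

    def model_spec(self) -> ModelSpec:
        return ModelSpec([law.block() for law in self.covariates])

    # ---- YAML round trip -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_strata": self.n_strata,
            "psus_per_stratum": self.psus_per_stratum,
            "households_per_psu": self.households_per_psu,
            "asset_count": self.asset_count,
            "true_beta_poor": [float(v) for v in self.true_beta_poor],
            "true_beta_nonpoor": [float(v) for v in self.true_beta_nonpoor],
            "psu_effect_sd": self.psu_effect_sd,
            "weight_scheme": self.weight_scheme,
            "seed": self.seed,
            "covariates": [
                {
                    "name": law.name,
                    "kind": law.kind,
                    "levels": list(law.levels),
                    "reference": law.reference,
                    "base_logits": list(law.base_logits),
                    "wealth_slopes": list(law.wealth_slopes),
                    "partner": law.partner,
                }
                for law in self.covariates
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        laws = [
            CovariateLaw(
                name=ld["name"],
                kind=ld.get("kind", "categorical"),
                levels=tuple(ld["levels"]),
                reference=ld["reference"],
                base_logits=tuple(ld["base_logits"]),
                wealth_slopes=tuple(ld["wealth_slopes"]),
                partner=bool(ld.get("partner", False)),
            )
            for ld in d["covariates"]
        ]
        return cls(
            n_strata=int(d["n_strata"]),
            psus_per_stratum=int(d["psus_per_stratum"]),
            households_per_psu=int(d["households_per_psu"]),
            asset_count=int(d["asset_count"]),
            true_beta_poor=np.asarray(d["true_beta_poor"], dtype=float),
            true_beta_nonpoor=np.asarray(d["true_beta_nonpoor"], dtype=float),
            covariates=laws,
            psu_effect_sd=float(d.get("psu_effect_sd", 0.0)),
            weight_scheme=d.get("weight_scheme", "uniform"),
            seed=int(d.get("seed", 0)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def compute_asset_index(assets, column_names=None) -> np.ndarray:
    """First principal-component score of the column-standardized asset matrix.

    The sign is fixed so the score correlates positively with the row sum of
    assets (more assets -> higher score); the score has mean zero.
    """
    A = np.asarray(assets, dtype=float)
    if A.ndim != 2 or A.shape[1] < 1:
        raise ValidationError("asset matrix must be 2-D with at least one column")
    if A.shape[0] < 2:
        raise ValidationError("need at least 2 households to build an asset index")
    if np.isnan(A).any():
        raise ValidationError("asset matrix must not contain missing values")
    names = list(column_names) if column_names is not None else [f"asset_{j}" for j in range(A.shape[1])]
    sd = A.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValidationError(f"zero-variance asset column(s): {[names[j] for j in dead]}")

    Z = (A - A.mean(axis=0)) / sd
    if Z.shape[1] == 1:
        score = Z[:, 0]
    else:
        # first right-singular vector of Z == leading eigenvector of corr(A)
        _, _, vt = np.linalg.svd(Z, full_matrices=False)
        score = Z @ vt[0]
    rowsum = A.sum(axis=1)
    orient = np.dot(score, rowsum - rowsum.mean())
    if orient == 0:
        orient = vt[0].sum() if Z.shape[1] > 1 else 1.0
    if orient < 0:
        score = -score
    return score - score.mean()


def _draw_levels(p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorized categorical draw; p is (n, L)."""
    u = rng.random(p.shape[0])
    cum = np.cumsum(p, axis=1)
    return (u[:, None] > cum).sum(axis=1)


def _design_from_levels(levels_by_block: dict, config: SyntheticConfig, n: int) -> np.ndarray:
    cols = [np.ones(n)]
    for law in config.covariates:
        idx = levels_by_block[law.name]
        for j, lv in enumerate(law.levels):
            if lv == law.reference:
                continue
            cols.append((idx == j).astype(float))
    return np.column_stack(cols)


def generate_population(config: SyntheticConfig, return_internals: bool = False):
    """Simulate one birth-level micro-data table.

    Same config and seed reproduce the identical table bit-for-bit.  The
    returned table carries raw assets and the PCA wealth index but no group
    labels; with ``return_internals=True`` a second dict exposes the latent
    wealth, the true design matrix, PSU effects, the group labels used for
    outcome generation and the true outcome probabilities under both
    coefficient vectors.
    """
    ss = np.random.SeedSequence(config.seed)
    s_wealth, s_assets, s_cov, s_psu, s_weight, s_outcome = (
        np.random.default_rng(c) for c in ss.spawn(6)
    )

    S, P, H = config.n_strata, config.psus_per_stratum, config.households_per_psu
    n = S * P * H
    stratum = np.repeat(np.arange(S), P * H)
    psu = np.repeat(np.arange(S * P), H)
    stratum_effect = np.linspace(-1.0, 1.0, S) if S > 1 else np.zeros(1)
    latent = stratum_effect[stratum] + s_wealth.standard_normal(n)

    # conditionally independent Bernoulli assets given latent wealth
    cuts = np.linspace(-1.0, 1.0, config.asset_count)
    asset_p = expit(cuts[None, :] + 1.5 * latent[:, None])
    assets = (s_assets.random((n, config.asset_count)) < asset_p).astype(int)
    wealth_index = compute_asset_index(assets)

    levels_by_block: dict[str, np.ndarray] = {}
    for law in config.covariates:
        levels_by_block[law.name] = _draw_levels(law.probs(latent), s_cov)

    if config.weight_scheme == "uniform":
        weight = np.ones(n)
    else:
        # PPS stand-in: PSU "population size" drives selection probability,
        # weight proportional to its inverse, normalized to mean 1
        sizes = s_weight.integers(50, 501, size=S * P).astype(float)
        w_psu = 1.0 / sizes
        w_psu *= (S * P) / w_psu.sum()
        weight = w_psu[psu]

    psu_effect = (
        s_psu.standard_normal(S * P) * config.psu_effect_sd
        if config.psu_effect_sd > 0
        else np.zeros(S * P)
    )
    u = psu_effect[psu]

    # group for the outcome process comes from the asset index via the same
    # weighted-quintile rule the analysis pipeline applies
    tmp = MicroData(pd.DataFrame({"wealth_index": wealth_index, "weight": weight}))
    grouped = assign_wealth_groups(tmp)
    group = grouped.frame["group"].to_numpy()
    quintile = grouped.frame["wealth_quintile"].to_numpy()

    X = _design_from_levels(levels_by_block, config, n)
    if X.shape[1] != config.true_beta_poor.size:
        raise ConfigError("beta length does not conform to the covariate design")
    eta_poor = X @ config.true_beta_poor + u
    eta_nonpoor = X @ config.true_beta_nonpoor + u
    p_poor = expit(eta_poor)
    p_nonpoor = expit(eta_nonpoor)
    p = np.where(group == POOR, p_poor, p_nonpoor)
    outcome = (s_outcome.random(n) < p).astype(int)

    frame = pd.DataFrame(
        {
            "outcome": outcome,
            "weight": weight,
            "stratum": [f"s{v}" for v in stratum],
            "psu": [f"c{v}" for v in psu],
            "wealth_index": wealth_index,
        }
    )
    for j in range(config.asset_count):
        frame[f"asset_{j}"] = assets[:, j]
    for law in config.covariates:
        frame[law.name] = np.asarray(law.levels, dtype=object)[levels_by_block[law.name]]

    micro = MicroData(frame)
    if not return_internals:
        return micro
    internals = {
        "latent": latent,
        "design": X,
        "psu_effect": u,
        "group": group,
        "quintile": quintile,
        "p_poor": p_poor,
        "p_nonpoor": p_nonpoor,
        "p_true": p,
    }
    return micro, internals


# ---------------------------------------------------------------------------
# Monte-Carlo oracle


def _cluster_se_of_wmean(v, w, psu) -> float:
    wt = w / w.sum()
    resid = wt * (v - np.sum(wt * v))
    _, inv = np.unique(psu, return_inverse=True)
    agg = np.zeros(inv.max() + 1)
    np.add.at(agg, inv, resid)
    return float(np.sqrt(np.sum(agg**2)))


def _diff_se(v_a, w_a, psu_a, v_b, w_b, psu_b) -> float:
    """SE of wmean(v_a) - wmean(v_b) with PSU clustering across both parts."""
    wa = w_a / w_a.sum()
    wb = w_b / w_b.sum()
    contrib = np.concatenate([wa * (v_a - np.sum(wa * v_a)), -wb * (v_b - np.sum(wb * v_b))])
    psu_all = np.concatenate([psu_a, psu_b])
    _, inv = np.unique(psu_all, return_inverse=True)
    agg = np.zeros(inv.max() + 1)
    np.add.at(agg, inv, contrib)
    return float(np.sqrt(np.sum(agg**2)))


@dataclass
class OracleDecomposition:
    """Ground-truth decomposition quantities from the generator's law."""

    poor_coverage: float
    nonpoor_coverage: float
    gap: float
    explained: dict[str, float]  # benchmark -> probability points
    unexplained: dict[str, float]
    se_poor_coverage: float
    se_nonpoor_coverage: float
    se_gap: float
    se_explained: dict[str, float]
    n: int

    def explained_share(self, benchmark: str) -> float:
        return self.explained[benchmark] / self.gap

    def explained_share_se(self, benchmark: str) -> float:
        # conservative delta-method bound
        g, e = abs(self.gap), self.explained[benchmark]
        return (self.se_explained[benchmark] + abs(e / g) * self.se_gap) / g


def oracle_expected_decomposition(
    config: SyntheticConfig, n_mc: int = 100_000, seed: int = 0
) -> OracleDecomposition:
    """Monte-Carlo expected coverages and explained portions under TRUE betas.

    Simulates a population of at least ``n_mc`` births from ``config``'s law
    (same strata/PSU structure, households scaled up), then averages true
    outcome probabilities — no outcome noise enters.  Benchmarks ``nonpoor``
    and ``poor`` are evaluated; no true pooled coefficient vector exists, so
    no pooled benchmark is reported.  Standard errors are PSU-clustered.
    """
    if n_mc < 10_000:
        raise ConfigError("n_mc must be at least 10,000")
    per_psu = max(
        config.households_per_psu,
        math.ceil(n_mc / (config.n_strata * config.psus_per_stratum)),
    )
    cfg = replace(config, households_per_psu=per_psu, seed=seed)
    micro, internals = generate_population(cfg, return_internals=True)

    w = micro.frame["weight"].to_numpy(dtype=float)
    psu = micro.frame["psu"].to_numpy()
    poor = internals["group"] == POOR
    nonpoor = ~poor
    p_p, p_np = internals["p_poor"], internals["p_nonpoor"]

    def wmean(v, m):
        return float(np.sum(w[m] * v[m]) / np.sum(w[m]))

    cov_poor = wmean(p_p, poor)
    cov_np = wmean(p_np, nonpoor)
    gap = cov_np - cov_poor
    explained = {
        "nonpoor": wmean(p_np, nonpoor) - wmean(p_np, poor),
        "poor": wmean(p_p, nonpoor) - wmean(p_p, poor),
    }
    se_explained = {
        "nonpoor": _diff_se(p_np[nonpoor], w[nonpoor], psu[nonpoor], p_np[poor], w[poor], psu[poor]),
        "poor": _diff_se(p_p[nonpoor], w[nonpoor], psu[nonpoor], p_p[poor], w[poor], psu[poor]),
    }
    return OracleDecomposition(
        poor_coverage=cov_poor,
        nonpoor_coverage=cov_np,
        gap=gap,
        explained=explained,
        unexplained={k: gap - v for k, v in explained.items()},
        se_poor_coverage=_cluster_se_of_wmean(p_p[poor], w[poor], psu[poor]),
        se_nonpoor_coverage=_cluster_se_of_wmean(p_np[nonpoor], w[nonpoor], psu[nonpoor]),
        se_gap=_diff_se(p_np[nonpoor], w[nonpoor], psu[nonpoor], p_p[poor], w[poor], psu[poor]),
        se_explained=se_explained,
        n=len(micro),
    )


# ---------------------------------------------------------------------------
# Ready-made configuration


def example_config(
    n_strata: int = 5,
    psus_per_stratum: int = 10,
    households_per_psu: int = 30,
    psu_effect_sd: float = 0.0,
    weight_scheme: str = "uniform",
    seed: int = 0,
) -> SyntheticConfig:
    """A mid-sized configuration with wealth-dependent covariates and
    genuinely different poor / nonpoor outcome processes."""
    laws = [
        CovariateLaw("distance", ("0", "1"), "0", (0.0, -0.3), (0.0, -0.8), kind="binary"),
        CovariateLaw(
            "mother_edu",
            ("none", "primary", "secondary", "higher"),
            "none",
            (0.0, 0.6, 1.0, 0.1),
            (0.0, 0.3, 1.0, 1.6),
        ),
        CovariateLaw(
            "partner_edu",
            ("none", "primary", "secondary", "higher"),
            "none",
            (0.0, 0.7, 0.8, 0.0),
            (0.0, 0.3, 0.9, 1.5),
            partner=True,
        ),
        CovariateLaw("tv", ("0", "1"), "0", (0.0, 0.3), (0.0, 1.0), kind="binary"),
        CovariateLaw(
            "birth_order", ("1", "2-4", ">4"), "2-4", (-0.2, 0.6, -0.3), (0.4, 0.0, -0.9)
        ),
        CovariateLaw(
            "religion", ("catholic", "islam", "other"), "catholic", (1.2, -0.6, 0.0), (0.0, -0.8, -0.2)
        ),
    ]
    beta_poor = np.array(
        [-0.9, -0.5, 0.2, 0.6, 1.0, 0.15, 0.5, 0.9, 0.4, 0.6, -0.5, -0.7, -0.2]
    )
    beta_nonpoor = np.array(
        [0.3, -0.3, 0.1, 0.4, 0.8, 0.1, 0.35, 0.7, 0.3, 0.5, -0.4, -0.5, -0.1]
    )
    return SyntheticConfig(
        n_strata=n_strata,
        psus_per_stratum=psus_per_stratum,
        households_per_psu=households_per_psu,
        asset_count=8,
        true_beta_poor=beta_poor,
        true_beta_nonpoor=beta_nonpoor,
        covariates=laws,
        psu_effect_sd=psu_effect_sd,
        weight_scheme=weight_scheme,
        seed=seed,
    )
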