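"""Micro-data I/O, wealth grouping, covariate coding and missing-data handling.

Turns raw birth-level records into estimation-ready design matrices.  The
canonical CSV schema has the design columns ``outcome`` (or the name declared
in the :class:`ModelSpec`), ``weight``, ``stratum``, ``psu`` and
``wealth_index`` and/or ``wealth_quintile``, followed by one column per
covariate block.  Covariate values are compared as strings, so integer and
string level codes round-trip identically through CSV.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .errors import CodingError, SchemaError, ValidationError

__all__ = [
    "Block",
    "ModelSpec",
    "MicroData",
    "DesignMatrix",
    "INTERCEPT",
    "MISSING_PARTNER",
    "read_microdata",
    "write_microdata",
    "weighted_quantile",
    "assign_wealth_groups",
    "build_design_matrix",
]

#: Name used for the leading intercept column and its pseudo-block.
INTERCEPT = "(intercept)"
#: Column/block name of the missing-partner-information indicator.
MISSING_PARTNER = "missing_partner"

POOR, NONPOOR = "poor", "nonpoor"

_DESIGN_COLUMNS = ("weight", "stratum", "psu")


@dataclass(frozen=True)
class Block:
    """One covariate block: a binary indicator or a categorical variable.

    ``partner`` marks blocks describing the mother's partner; those are the
    blocks covered by the missing-partner-dummy policy.
    """

    name: str
    kind: str  # "binary" | "categorical"
    levels: tuple
    reference: object
    partner: bool = False

    def __post_init__(self):
        if self.kind not in ("binary", "categorical"):
            raise ValidationError(f"block {self.name!r}: unknown kind {self.kind!r}")
        object.__setattr__(self, "levels", tuple(self.levels))
        if self.kind == "binary" and len(self.levels) != 2:
            raise ValidationError(f"binary block {self.name!r} must have exactly 2 levels")
        if len(self.levels) < 2:
            raise ValidationError(f"block {self.name!r} needs at least 2 levels")
        if self.reference not in self.levels:
            raise ValidationError(
                f"block {self.name!r}: reference {self.reference!r} not among levels {self.levels}"
            )

    @property
    def coded_levels(self) -> tuple:
        """Non-reference levels, in declared order; one dummy column each."""
        return tuple(lv for lv in self.levels if lv != self.reference)


@dataclass
class ModelSpec:
    """Ordered covariate blocks plus outcome name and missing-partner policy."""

    blocks: list[Block]
    outcome_name: str = "outcome"
    missing_partner_policy: str = "dummy"  # "dummy" | "drop"

    def __post_init__(self):
        names = [b.name for b in self.blocks]
        if len(set(names)) != len(names):
            raise ValidationError("block names must be unique")
        if self.missing_partner_policy not in ("dummy", "drop"):
            raise ValidationError(
                f"unknown missing_partner_policy {self.missing_partner_policy!r}"
            )

    def block(self, name: str) -> Block:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(name)

    @property
    def block_names(self) -> list[str]:
        return [b.name for b in self.blocks]

    def with_reference(self, block_name: str, reference) -> "ModelSpec":
        """Copy of the spec with one block's reference level swapped."""
        blocks = [
            replace(b, reference=reference) if b.name == block_name else b
            for b in self.blocks
        ]
        return ModelSpec(blocks, self.outcome_name, self.missing_partner_policy)

    # ---- YAML round trip -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "outcome_name": self.outcome_name,
            "missing_partner_policy": self.missing_partner_policy,
            "blocks": [
                {
                    "name": b.name,
                    "kind": b.kind,
                    "levels": list(b.levels),
                    "reference": b.reference,
                    "partner": b.partner,
                }
                for b in self.blocks
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        blocks = [
            Block(
                name=bd["name"],
                kind=bd["kind"],
                levels=tuple(bd["levels"]),
                reference=bd["reference"],
                partner=bool(bd.get("partner", False)),
            )
            for bd in d["blocks"]
        ]
        return cls(
            blocks,
            outcome_name=d.get("outcome_name", "outcome"),
            missing_partner_policy=d.get("missing_partner_policy", "dummy"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class MicroData:
    """Birth-level micro-data table.

    Thin wrapper over a :class:`pandas.DataFrame` using the canonical column
    names.  Covariate columns hold string level codes (or NaN for missing).
    """

    frame: pd.DataFrame

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def has_groups(self) -> bool:
        return "group" in self.frame.columns

    def group_mask(self, group: str) -> np.ndarray:
        if not self.has_groups:
            raise ValidationError("wealth groups not assigned; call assign_wealth_groups first")
        return (self.frame["group"] == group).to_numpy()


@dataclass
class DesignMatrix:
    """Numeric design matrix with a leading intercept column.

    ``column_blocks[j]`` names the block that produced column ``j``
    (``INTERCEPT`` for column 0, ``MISSING_PARTNER`` for the missing-partner
    indicator).  ``row_ids`` are positional indices into the source table's
    rows; ``y``, ``weights``, ``psu`` and (when available) ``groups`` are
    aligned to the retained rows.
    """

    values: np.ndarray
    columns: list[str]
    column_blocks: list[str]
    row_ids: np.ndarray
    y: np.ndarray
    weights: np.ndarray
    psu: np.ndarray
    groups: np.ndarray | None = None
    n_dropped: int = 0

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def block_columns(self, block: str) -> np.ndarray:
        """Positional indices of the columns belonging to ``block``."""
        return np.flatnonzero(np.asarray(self.column_blocks) == block)

    @property
    def blocks(self) -> list[str]:
        """Switchable block names in column order (intercept excluded)."""
        seen: list[str] = []
        for b in self.column_blocks:
            if b != INTERCEPT and b not in seen:
                seen.append(b)
        return seen

    def subset(self, mask: np.ndarray) -> "DesignMatrix":
        mask = np.asarray(mask, dtype=bool)
        return DesignMatrix(
            values=self.values[mask],
            columns=self.columns,
            column_blocks=self.column_blocks,
            row_ids=self.row_ids[mask],
            y=self.y[mask],
            weights=self.weights[mask],
            psu=self.psu[mask],
            groups=None if self.groups is None else self.groups[mask],
            n_dropped=0,
        )

    def split_groups(self) -> tuple["DesignMatrix", "DesignMatrix"]:
        """(poor, nonpoor) row subsets, using the aligned ``groups`` labels."""
        if self.groups is None:
            raise ValidationError("design matrix carries no group labels")
        return self.subset(self.groups == POOR), self.subset(self.groups == NONPOOR)


# ---------------------------------------------------------------------------
# I/O


def _is_missing(series: pd.Series) -> pd.Series:
    return series.isna() | (series.astype(str).str.strip() == "")


def read_microdata(source, spec: ModelSpec) -> MicroData:
    """Read and validate a micro-data CSV against ``spec``.

    ``source`` may be a path or a text stream.  Mandatory columns are the
    outcome, ``weight``, ``stratum``, ``psu`` and at least one of
    ``wealth_index`` / ``wealth_quintile``.  Offending rows are reported by
    1-based data-row number.
    """
    if isinstance(source, (str, bytes)) and "\n" in str(source):
        source = io.StringIO(str(source))
    df = pd.read_csv(source, dtype=str, skipinitialspace=True)

    required = [spec.outcome_name, *_DESIGN_COLUMNS]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column {col!r}")
    if "wealth_index" not in df.columns and "wealth_quintile" not in df.columns:
        raise SchemaError("need a 'wealth_index' or 'wealth_quintile' column")
    for b in spec.blocks:
        if b.name not in df.columns:
            raise SchemaError(f"missing covariate column {b.name!r}")

    out = pd.DataFrame(index=df.index)

    y = pd.to_numeric(df[spec.outcome_name], errors="coerce")
    bad = df.index[~y.isin([0, 1])].tolist()
    if bad:
        raise ValidationError(
            f"outcome {spec.outcome_name!r} must be 0/1; offending rows: "
            f"{[i + 1 for i in bad]}"
        )
    out[spec.outcome_name] = y.astype(int)

    w = pd.to_numeric(df["weight"], errors="coerce")
    bad = df.index[~(w > 0)].tolist()
    if bad:
        raise ValidationError(f"weight must be positive; offending rows: {[i + 1 for i in bad]}")
    out["weight"] = w.astype(float)

    out["stratum"] = df["stratum"].astype(str)
    out["psu"] = df["psu"].astype(str)

    if "wealth_index" in df.columns:
        wi = pd.to_numeric(df["wealth_index"], errors="coerce")
        if wi.isna().any():
            bad = df.index[wi.isna()].tolist()
            raise ValidationError(
                f"non-numeric wealth_index; offending rows: {[i + 1 for i in bad]}"
            )
        out["wealth_index"] = wi.astype(float)
    if "wealth_quintile" in df.columns:
        q = pd.to_numeric(df["wealth_quintile"], errors="coerce")
        bad = df.index[~q.isin([1, 2, 3, 4, 5])].tolist()
        if bad:
            raise ValidationError(
                f"wealth_quintile must be 1..5; offending rows: {[i + 1 for i in bad]}"
            )
        out["wealth_quintile"] = q.astype(int)
        out["group"] = np.where(out["wealth_quintile"] <= 2, POOR, NONPOOR)
    if "household" in df.columns:
        out["household"] = df["household"].astype(str)

    for b in spec.blocks:
        out[b.name] = df[b.name]

    return MicroData(out.reset_index(drop=True))


def write_microdata(micro: MicroData, target) -> None:
    """Write the table as canonical CSV (UTF-8, comma, '.' decimal)."""
    micro.frame.to_csv(target, index=False)


# ---------------------------------------------------------------------------
# Wealth grouping


def weighted_quantile(values, weights, q) -> float:
    """Weighted-CDF quantile: smallest value whose cumulative weight share >= q."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights <= 0):
        raise ValidationError("weights must be positive")
    order = np.argsort(values, kind="stable")
    cum = np.cumsum(weights[order]) / weights.sum()
    idx = int(np.searchsorted(cum, q - 1e-12))
    return float(values[order][min(idx, len(values) - 1)])


def assign_wealth_groups(micro: MicroData) -> MicroData:
    """Fill ``wealth_quintile`` and ``group`` from weighted quintiles of the index.

    Boundaries are weighted quantiles of ``wealth_index`` at 0.2/0.4/0.6/0.8
    over households (rows, or unique ``household`` ids when present); tied
    values share a quintile.  ``group`` is ``poor`` iff quintile <= 2.
    """
    df = micro.frame.copy()
    if "wealth_index" not in df.columns:
        raise ValidationError("wealth_index column required to assign quintiles")
    idx = df["wealth_index"].to_numpy(dtype=float)
    w = df["weight"].to_numpy(dtype=float)
    if np.ptp(idx) == 0:
        raise ValidationError("wealth_index is constant; quintiles undefined")

    if "household" in df.columns:
        hh = df.drop_duplicates("household")
        hv = hh["wealth_index"].to_numpy(dtype=float)
        hw = hh["weight"].to_numpy(dtype=float)
    else:
        hv, hw = idx, w

    cuts = [weighted_quantile(hv, hw, q) for q in (0.2, 0.4, 0.6, 0.8)]
    quintile = np.ones(len(df), dtype=int)
    for c in cuts:
        quintile += (idx > c).astype(int)
    df["wealth_quintile"] = quintile
    df["group"] = np.where(quintile <= 2, POOR, NONPOOR)
    return MicroData(df)


# ---------------------------------------------------------------------------
# Design matrix


def build_design_matrix(micro: MicroData, spec: ModelSpec) -> DesignMatrix:
    """Dummy-code covariate blocks against their reference levels.

    Records missing any non-partner covariate are dropped (listwise).  Under
    ``missing_partner_policy="dummy"``, records missing a partner field are
    retained with all partner dummies at 0 and a trailing ``missing_partner``
    indicator at 1 (the indicator column is emitted only when at least one
    such record is retained, so fully observed data keep a full-rank design).
    """
    df = micro.frame
    for b in spec.blocks:
        if b.name not in df.columns:
            raise SchemaError(f"missing covariate column {b.name!r}")

    n = len(df)
    missing = {b.name: _is_missing(df[b.name]).to_numpy() for b in spec.blocks}
    partner_names = [b.name for b in spec.blocks if b.partner]

    if spec.missing_partner_policy == "dummy" and partner_names:
        miss_partner = np.zeros(n, dtype=bool)
        for name in partner_names:
            miss_partner |= missing[name]
        drop = np.zeros(n, dtype=bool)
        for b in spec.blocks:
            if not b.partner:
                drop |= missing[b.name]
    else:
        miss_partner = np.zeros(n, dtype=bool)
        drop = np.zeros(n, dtype=bool)
        for b in spec.blocks:
            drop |= missing[b.name]
    keep = ~drop

    cols = [np.ones(n)]
    names = [INTERCEPT]
    block_map = [INTERCEPT]
    for b in spec.blocks:
        obs = ~missing[b.name]
        vals = df[b.name].astype(str).str.strip()
        declared = {str(lv) for lv in b.levels}
        seen = set(vals[obs & keep].unique())
        stray = sorted(seen - declared)
        if stray:
            raise CodingError(
                f"block {b.name!r}: value(s) {stray} outside declared levels {list(b.levels)}"
            )
        for lv in b.coded_levels:
            col = np.where(obs, (vals == str(lv)).to_numpy(), False).astype(float)
            if b.partner:
                col[miss_partner] = 0.0
            cols.append(col)
            names.append(f"{b.name}[{lv}]")
            block_map.append(b.name)

    if spec.missing_partner_policy == "dummy" and partner_names and miss_partner[keep].any():
        cols.append(miss_partner.astype(float))
        names.append(MISSING_PARTNER)
        block_map.append(MISSING_PARTNER)

    X = np.column_stack(cols)[keep]
    row_ids = np.flatnonzero(keep)

    y = pd.to_numeric(df[spec.outcome_name], errors="coerce").to_numpy(dtype=float)[keep]
    if not np.isin(y, [0.0, 1.0]).all():
        raise ValidationError(f"outcome {spec.outcome_name!r} must be binary 0/1")
    weights = df["weight"].to_numpy(dtype=float)[keep]
    if np.any(weights <= 0):
        raise ValidationError("weights must be positive")
    psu = df["psu"].astype(str).to_numpy()[keep]
    groups = df["group"].astype(str).to_numpy()[keep] if "group" in df.columns else None

    return DesignMatrix(
        values=X,
        columns=names,
        column_blocks=block_map,
        row_ids=row_ids,
        y=y,
        weights=weights,
        psu=psu,
        groups=groups,
        n_dropped=int(drop.sum()),
    )
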