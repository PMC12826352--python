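"""Subject-level survival data with a common-predictor / within-cluster covariate split.

Each subject carries a follow-up time ``T_i``, an event indicator ``delta_i``
(1 = event observed, 0 = censored), a continuous exposure ``A_i``, and two
covariate blocks: ``Z`` (common predictors whose exposure effect is shared
across latent clusters) and ``V`` (covariates whose exposure effect may vary
by cluster). Either block may be empty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["SurvivalDataset", "load_dataset", "write_dataset", "validate_dataset"]


@dataclass(frozen=True)
class SurvivalDataset:
    """Validated rectangular survival table.

    Parameters
    ----------
    time : array of shape (n,)
        Strictly positive follow-up times. Ties are legal.
    event : array of shape (n,)
        Event indicators in {0, 1}.
    exposure : array of shape (n,)
        Continuous exposure A.
    z : array of shape (n, p_z)
        Common predictors (may have zero columns).
    v : array of shape (n, p_v)
        Within-cluster covariates (may have zero columns).
    """

    time: np.ndarray
    event: np.ndarray
    exposure: np.ndarray
    z: np.ndarray = field(default=None)  # type: ignore[assignment]
    v: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event, dtype=float)
        exposure = np.asarray(self.exposure, dtype=float)
        n = time.shape[0]
        z = _as_2d(self.z, n)
        v = _as_2d(self.v, n)
        for name, val in (("time", time), ("event", event), ("exposure", exposure),
                          ("z", z), ("v", v)):
            object.__setattr__(self, name, val)
        problems = validate_dataset(self)
        if problems:
            raise ValueError("invalid survival dataset: " + "; ".join(problems))

    @property
    def n(self) -> int:
        return int(self.time.shape[0])

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def covariates(self) -> np.ndarray:
        """Outcome-model design x~ = (a, z, v), shape (n, 1 + p_z + p_v)."""
        return np.column_stack([self.exposure, self.z, self.v])

    def to_frame(self) -> pd.DataFrame:
        cols = {"time": self.time, "event": self.event.astype(int),
                "exposure": self.exposure}
        for j in range(self.z.shape[1]):
            cols[f"z{j + 1}"] = self.z[:, j]
        for j in range(self.v.shape[1]):
            cols[f"v{j + 1}"] = self.v[:, j]
        return pd.DataFrame(cols)


def _as_2d(x, n: int) -> np.ndarray:
    if x is None:
        return np.empty((n, 0), dtype=float)
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return x


def validate_dataset(ds: SurvivalDataset) -> list[str]:
    """Return human-readable invariant violations (empty list when valid)."""
    out: list[str] = []
    n = ds.time.shape[0]
    if n < 2:
        out.append("n >= 2 required")
    for name in ("event", "exposure"):
        if getattr(ds, name).shape[0] != n:
            out.append(f"length of '{name}' differs from 'time'")
    for name in ("z", "v"):
        arr = getattr(ds, name)
        if arr.shape[0] != n:
            out.append(f"row count of '{name}' differs from 'time'")
    for name in ("time", "event", "exposure", "z", "v"):
        if not np.all(np.isfinite(getattr(ds, name))):
            out.append(f"non-finite value in '{name}'")
    if np.any(ds.time <= 0):
        rows = np.flatnonzero(ds.time <= 0)
        out.append(f"non-positive time at row(s) {rows.tolist()}")
    bad = ~np.isin(ds.event, (0.0, 1.0))
    if np.any(bad):
        rows = np.flatnonzero(bad)
        out.append(f"event not in {{0,1}} at row(s) {rows.tolist()}")
    return out


def load_dataset(
    path: str | Path,
    time_col: str = "time",
    event_col: str = "event",
    exposure_col: str = "exposure",
    z_cols: Sequence[str] = (),
    v_cols: Sequence[str] = (),
) -> SurvivalDataset:
    """Read a CSV into a validated :class:`SurvivalDataset`, preserving row order.

    Raises
    ------
    KeyError
        If a named column is absent from the file.
    ValueError
        If a named column contains missing values or an invariant fails
        (the message cites the offending rows).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    wanted = [time_col, event_col, exposure_col, *z_cols, *v_cols]
    missing = [c for c in wanted if c not in df.columns]
    if missing:
        raise KeyError(f"column(s) {missing} not found in {path}")
    sub = df[wanted]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise ValueError(f"missing values in column(s) {bad}; complete cases required")
    return SurvivalDataset(
        time=df[time_col].to_numpy(float),
        event=df[event_col].to_numpy(float),
        exposure=df[exposure_col].to_numpy(float),
        z=df[list(z_cols)].to_numpy(float) if z_cols else None,
        v=df[list(v_cols)].to_numpy(float) if v_cols else None,
    )


def write_dataset(ds: SurvivalDataset, path: str | Path) -> None:
    """Write as CSV with canonical column names (time, event, exposure, z*, v*)."""
    # %.17g keeps the round-trip bit-exact
    ds.to_frame().to_csv(path, index=False, float_format="%.17g")
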