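"""CSV ingestion, run configuration and fit persistence.

The single input dialect is a daily CSV with ISO-8601 dates::

    date,wt,at,q
    1995-01-01,8.4,6.1,5.2
    1995-01-02,,5.8,6.0        # empty/NA cells mark missing values

``q`` (discharge, m^3/s) is optional and natural-log transformed at
ingestion; zero or negative flows are shifted by a small epsilon before
logging, with a warning.  Fits are persisted as a directory of plain-text
files (a wide draws table, the convergence report, the training data and a
JSON sidecar) that reload into a fully functional :class:`PosteriorDraws`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

from .core import DailySeries, build_windows
from .inference import (
    ConvergenceReport,
    McmcConfig,
    PosteriorDraws,
    Prior,
    PriorSpec,
)

logger = logging.getLogger("streamtemp")

__all__ = ["RunConfig", "read_input", "write_input", "save_fit", "load_fit"]

#: shift applied to non-positive discharge before the log transform (m^3/s)
Q_EPSILON = 0.001


@dataclass
class RunConfig:
    """Validated options of one command-line run."""

    model_variant: str = "M2"
    use_discharge: bool = True
    preset: str = "desk"  # "desk" | "paper"
    seed: int = 0
    train_fraction: float = 2.0 / 3.0
    warming_min: float = 0.0
    warming_max: float = 5.0
    warming_step: float = 0.5
    share_intercept: bool = False
    n_chains: Optional[int] = None
    n_burnin: Optional[int] = None
    n_keep: Optional[int] = None
    thin: Optional[int] = None

    def __post_init__(self) -> None:
        if self.model_variant not in ("M1", "M2"):
            raise ValueError("model_variant must be 'M1' or 'M2'")
        if self.preset not in ("desk", "paper"):
            raise ValueError("preset must be 'desk' or 'paper'")
        if not 0.1 < self.train_fraction < 0.95:
            raise ValueError("train_fraction must lie in (0.1, 0.95)")
        if self.warming_step <= 0 or self.warming_max <= self.warming_min:
            raise ValueError("invalid warming grid")

    def mcmc(self) -> McmcConfig:
        base = McmcConfig.desk if self.preset == "desk" else McmcConfig.paper
        cfg = base(variant=self.model_variant, use_discharge=self.use_discharge,
                   share_intercept=self.share_intercept, seed=self.seed)
        for nm in ("n_chains", "n_burnin", "n_keep", "thin"):
            v = getattr(self, nm)
            if v is not None:
                setattr(cfg, nm, int(v))
        cfg.__post_init__()
        return cfg

    def warming_grid(self) -> np.ndarray:
        return np.arange(self.warming_min, self.warming_max + 1e-9, self.warming_step)


# ---------------------------------------------------------------------------
# input tables
# ---------------------------------------------------------------------------


def read_input(path, q_epsilon: float = Q_EPSILON) -> Dict[str, DailySeries]:
    """Read a daily CSV into validated series (WT, AT and optionally LOGQ).

    Non-consecutive calendars are completed with all-missing rows; duplicate
    or unparseable dates are rejected with their row numbers.
    """
    path = Path(path)
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("date", "wt", "at"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    dates = pd.to_datetime(df["date"], format="%Y-%m-%d", errors="coerce")
    if dates.isna().any():
        rows = (np.flatnonzero(dates.isna()) + 2)[:5]  # header is line 1
        raise ValueError(f"{path}: unparseable ISO dates at lines {list(rows)}")
    dup = dates.duplicated()
    if dup.any():
        rows = (np.flatnonzero(dup) + 2)[:5]
        raise ValueError(f"{path}: duplicate dates at lines {list(rows)}")
    order = np.argsort(dates.to_numpy())
    df = df.iloc[order].reset_index(drop=True)
    dates = dates.iloc[order]
    full = pd.date_range(dates.iloc[0], dates.iloc[-1], freq="D")
    df = df.set_index(pd.DatetimeIndex(dates)).reindex(full)

    def series(col, kind):
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        mask = np.isfinite(vals)
        return vals, mask

    wt_vals, wt_mask = series("wt", "WT")
    if not wt_mask.any():
        raise ValueError(f"{path}: water-temperature column is entirely missing")
    at_vals, at_mask = series("at", "AT")
    out = {
        "WT": DailySeries(full, np.where(wt_mask, wt_vals, np.nan), wt_mask, "WT"),
        "AT": DailySeries(full, np.where(at_mask, at_vals, np.nan), at_mask, "AT"),
    }
    if "q" in df.columns:
        q_vals, q_mask = series("q", "LOGQ")
        n_shift = int(np.sum(q_mask & (q_vals <= 0)))
        if n_shift:
            logger.warning("%s: %d non-positive discharge values shifted by "
                           "%g m^3/s before the log transform", path, n_shift, q_epsilon)
        q_pos = np.where(q_mask & (q_vals > 0), q_vals, q_epsilon)
        q_log = np.where(q_mask, np.log(q_pos), np.nan)
        out["LOGQ"] = DailySeries(full, q_log, q_mask, "LOGQ")
    else:
        logger.warning("%s: no discharge column found; the model will run "
                       "with air temperature as the only covariate", path)
    for kind, s in out.items():
        logger.info("%s: %s spans %s..%s, %.1f%% missing", path, kind,
                    s.dates[0], s.dates[-1], 100 * s.missing_fraction)
    return out


def write_input(path, data: Mapping[str, DailySeries]) -> None:
    """Write series to the input CSV dialect (discharge back on m^3/s scale)."""
    wt = data["WT"]
    cols = {"date": pd.DatetimeIndex(wt.dates).strftime("%Y-%m-%d"),
            "wt": np.where(wt.observed_mask, wt.values, np.nan),
            "at": np.where(data["AT"].observed_mask, data["AT"].values, np.nan)}
    if "LOGQ" in data:
        q = data["LOGQ"]
        cols["q"] = np.where(q.observed_mask, np.exp(q.values), np.nan)
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.4f")


# ---------------------------------------------------------------------------
# fit persistence
# ---------------------------------------------------------------------------


def _priors_to_json(priors: PriorSpec) -> dict:
    out = {}
    for nm, p in priors.items():
        out[nm] = {"family": p.family, "loc": np.asarray(p.loc).tolist(),
                   "scale": np.asarray(p.scale).tolist()}
    return out


def _priors_from_json(obj: dict) -> PriorSpec:
    return PriorSpec({nm: Prior(d["family"], np.asarray(d["loc"]),
                                np.asarray(d["scale"])) for nm, d in obj.items()})


def save_fit(outdir, draws: PosteriorDraws, report: Optional[ConvergenceReport] = None,
             float_format: str = "%.6g") -> Path:
    """Persist a fit as plain-text files in ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    draws.to_dataframe().to_csv(outdir / "draws.csv", index=False,
                                float_format=float_format)
    if report is not None:
        report.table.to_csv(outdir / "convergence.csv", index=False,
                            float_format="%.4f")
    # training data, keeping discharge on the log scale to avoid a lossy
    # exp/log round trip
    meta = draws.meta
    data = meta["data"]
    wt = data["WT"]
    cols = {"date": pd.DatetimeIndex(wt.dates).strftime("%Y-%m-%d")}
    for key, col in (("WT", "wt"), ("AT", "at"), ("LOGQ", "logq")):
        if key in data:
            s = data[key]
            cols[col] = np.where(s.observed_mask, s.values, np.nan)
    pd.DataFrame(cols).to_csv(outdir / "training_data.csv", index=False,
                              float_format="%.6f")
    mc: McmcConfig = meta["mcmc"]
    sidecar = {
        "mcmc": asdict(mc),
        "priors": _priors_to_json(meta["priors"]),
        "format": 1,
    }
    (outdir / "meta.json").write_text(json.dumps(sidecar, indent=1))
    logger.info("fit saved to %s", outdir)
    return outdir


def load_fit(outdir) -> PosteriorDraws:
    """Reload a fit saved by :func:`save_fit`."""
    outdir = Path(outdir)
    sidecar = json.loads((outdir / "meta.json").read_text())
    mc = McmcConfig(**sidecar["mcmc"])
    priors = _priors_from_json(sidecar["priors"])

    tr = pd.read_csv(outdir / "training_data.csv")
    dates = pd.DatetimeIndex(pd.to_datetime(tr["date"]))
    data = {}
    for key, col in (("WT", "wt"), ("AT", "at"), ("LOGQ", "logq")):
        if col in tr.columns:
            vals = tr[col].to_numpy(dtype=float)
            mask = np.isfinite(vals)
            data[key] = DailySeries(dates, vals, mask, key)
    windows = build_windows(dates)

    wide = pd.read_csv(outdir / "draws.csv")
    C = int(wide["chain"].max()) + 1
    N = int(wide["iteration"].max()) + 1
    arrays: Dict[str, np.ndarray] = {}
    labels: Dict[str, list] = {}
    groups: Dict[str, list] = {}
    for col in wide.columns:
        if col in ("chain", "iteration"):
            continue
        if col.endswith("]") and "[" in col:
            base, lab = col[:-1].split("[", 1)
            groups.setdefault(base, []).append((lab, col))
        else:
            arrays[col] = wide[col].to_numpy().reshape(C, N)
    for base, items in groups.items():
        labels[base] = [lab for lab, _ in items]
        block = np.stack([wide[col].to_numpy().reshape(C, N) for _, col in items],
                         axis=2)
        arrays[base] = block
    missing_idx = {
        kind: np.flatnonzero(~data[kind].observed_mask) if kind in data
        else np.array([], dtype=int)
        for kind in ("WT", "AT", "LOGQ")
    }
    meta = {"windows": windows, "data": data, "mcmc": mc,
            "config": mc.model_config, "priors": priors,
            "missing_idx": missing_idx}
    return PosteriorDraws(arrays, labels, meta)
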