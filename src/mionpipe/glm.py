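"""Voxelwise GLM for the block-design passive-viewing task.

Design matrices carry one MION-convolved boxcar per probe condition
(condition x hemifield for the relevant scan type), 17 nuisance regressors
(12 motion parameters and derivatives, unconvolved; reward, blinks and the
three eye-position traces, MION-convolved), and Legendre drift terms up to
order 4. The first three volumes of every run are excluded (magnetization
transient) and rows of censored blocks are dropped. Betas are expressed in
percent signal change from the voxel mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synth import (
    MionKernel,
    MOTION_COLUMNS,
    NUISANCE_COLUMNS,
    ScanDesign,
    SimulatedRun,
    condition_regressors,
    conditions_for,
    convolve_trace_tr,
)

DRIFT_ORDER = 4


# ---------------------------------------------------------------------------
# percent change
# ---------------------------------------------------------------------------

def to_percent_change(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Transform a (..., t) series to percent change from the temporal mean.

    Voxels whose mean is not strictly positive cannot be normalized; they
    are zeroed and flagged False in the returned validity mask.
    """
    data = np.asarray(data, float)
    mean = data.mean(axis=-1)
    scale = np.abs(data).max() if data.size else 1.0
    valid = mean > 1e-9 * max(scale, 1.0)
    safe = np.where(valid, mean, 1.0)
    pct = 100.0 * (data / safe[..., None] - 1.0)
    pct[~valid] = 0.0
    return pct, valid


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    frame: pd.DataFrame             # rows = kept volumes, named columns
    rows: np.ndarray                # volume indices kept
    task_columns: list[str]
    nuisance_columns: list[str]
    drift_columns: list[str]
    scan_type: str

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def _legendre_drift(n_total: int, rows: np.ndarray) -> dict[str, np.ndarray]:
    """Legendre polynomials order 0..DRIFT_ORDER over the full run length,
    evaluated at the kept rows (detrending basis is defined on run time)."""
    x = np.linspace(-1.0, 1.0, n_total)
    cols = {}
    for k in range(DRIFT_ORDER + 1):
        coeffs = np.zeros(k + 1)
        coeffs[k] = 1.0
        cols[f"drift_{k}"] = np.polynomial.legendre.legval(x, coeffs)[rows]
    return cols


def build_design_matrix(
    events: pd.DataFrame,
    nuisance: pd.DataFrame,
    kernel: MionKernel,
    scan_type: str,
    design: ScanDesign,
) -> DesignMatrix:
    """Assemble the per-run design matrix.

    Task and non-motion nuisance columns are MION-convolved; motion columns
    are not. The first ``design.n_discard_trs`` rows and all rows belonging
    to excluded blocks are dropped.
    """
    conds = conditions_for(scan_type)
    known = set(conds) | {"base"}
    bad = set(events.trial_type) - known
    if bad:
        raise ValueError(f"unknown trial_type(s) for {scan_type} scan: {sorted(bad)}")
    n_vol = design.n_volumes
    if len(nuisance) != n_vol:
        raise ValueError("nuisance traces must have one row per volume")

    task = condition_regressors(design, kernel, events)

    keep = np.ones(n_vol, bool)
    keep[: design.n_discard_trs] = False
    tpb = design.trs_per_block
    for _, row in events[events.excluded.astype(bool)].iterrows():
        i0 = int(round(row.onset / design.tr_s))
        keep[i0 : i0 + tpb] = False
    rows = np.flatnonzero(keep)

    cols: dict[str, np.ndarray] = {}
    for c in conds:
        cols[c] = task[c].to_numpy()[rows]
    for name in NUISANCE_COLUMNS:
        trace = nuisance[name].to_numpy()
        if name not in MOTION_COLUMNS:
            trace = convolve_trace_tr(trace, kernel, design.tr_s)
        cols[name] = trace[rows]
    cols.update(_legendre_drift(n_vol, rows))

    for name, col in cols.items():
        if not np.any(col != 0):
            raise ValueError(f"design column {name!r} is identically zero")
    frame = pd.DataFrame(cols)
    return DesignMatrix(
        frame=frame,
        rows=rows,
        task_columns=list(conds),
        nuisance_columns=list(NUISANCE_COLUMNS),
        drift_columns=[f"drift_{k}" for k in range(DRIFT_ORDER + 1)],
        scan_type=scan_type,
    )


def build_visual_design(
    events: pd.DataFrame,
    nuisance: pd.DataFrame,
    kernel: MionKernel,
    design: ScanDesign,
) -> DesignMatrix:
    """Single probe-vs-base regressor plus the same nuisance/drift columns.

    The resulting "visual" beta measures overall responsivity to probe
    blocks and is orthogonal to condition and hemifield labels by
    construction (all probe conditions collapse into one regressor).
    """
    ev = events.copy()
    ev.loc[ev.trial_type != "base", "trial_type"] = "probe"
    probe_design = ScanDesign(
        scan_type=design.scan_type,
        block_types=design.block_types,
        tr_s=design.tr_s,
        block_s=design.block_s,
        n_discard_trs=design.n_discard_trs,
    )
    n_fine = int(round(design.n_volumes * design.tr_s / kernel.dt))
    t_fine = np.arange(n_fine) * kernel.dt
    box = np.zeros(n_fine)
    for _, row in ev[ev.trial_type == "probe"].iterrows():
        box[(t_fine >= row.onset) & (t_fine < row.onset + row.duration)] = 1.0
    conv = kernel.convolve(box)
    vol_idx = (np.arange(design.n_volumes) * design.tr_s / kernel.dt).astype(int)
    probe = conv[vol_idx]

    X = build_design_matrix(events, nuisance, kernel, design.scan_type, probe_design)
    frame = X.frame.drop(columns=X.task_columns)
    frame.insert(0, "probe", probe[X.rows])
    return DesignMatrix(
        frame=frame,
        rows=X.rows,
        task_columns=["probe"],
        nuisance_columns=X.nuisance_columns,
        drift_columns=X.drift_columns,
        scan_type=design.scan_type,
    )


# ---------------------------------------------------------------------------
# OLS fit
# ---------------------------------------------------------------------------

@dataclass
class GlmResult:
    betas: np.ndarray               # (voxels, columns), percent units
    tstats: np.ndarray              # (voxels, columns)
    residuals: np.ndarray           # (voxels, rows)
    dof: int
    columns: list[str]
    design: DesignMatrix = field(repr=False, default=None)
    xtx_inv: np.ndarray = field(repr=False, default=None)
    sigma2: np.ndarray = field(repr=False, default=None)
    valid: np.ndarray = field(repr=False, default=None)
    shape: tuple = None             # spatial shape if input was a volume

    def beta(self, column: str) -> np.ndarray:
        b = self.betas[:, self.columns.index(column)]
        return b.reshape(self.shape) if self.shape else b

    def beta_volume(self, column: str) -> np.ndarray:
        return self.beta(column)


def _collinear_columns(X: np.ndarray, columns: list[str]) -> list[str]:
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    return [columns[i] for i in np.flatnonzero(diag < tol)]


def fit_glm(run, X: DesignMatrix) -> GlmResult:
    """Voxelwise OLS of percent-change data against the design matrix.

    ``run`` is a SimulatedRun or a (..., t) array of raw-signal series.
    """
    data = run.data if isinstance(run, SimulatedRun) else np.asarray(run, float)
    shape = data.shape[:-1]
    pct, valid = to_percent_change(data.reshape(-1, data.shape[-1]))
    Y = pct[:, X.rows]

    M = X.matrix
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[1]:
        bad = _collinear_columns(M, X.columns)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    if M.shape[0] != Y.shape[1]:
        raise ValueError("design rows do not match usable volumes")

    xtx_inv = np.linalg.inv(M.T @ M)
    betas = Y @ M @ xtx_inv
    resid = Y - betas @ M.T
    dof = M.shape[0] - rank
    sigma2 = (resid**2).sum(axis=1) / dof
    se = np.sqrt(np.outer(sigma2, np.diag(xtx_inv)))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstats = np.where(se > 0, betas / se, 0.0)
    return GlmResult(
        betas=betas,
        tstats=tstats,
        residuals=resid,
        dof=dof,
        columns=X.columns,
        design=X,
        xtx_inv=xtx_inv,
        sigma2=sigma2,
        valid=valid,
        shape=shape if len(shape) > 1 else None,
    )


# ---------------------------------------------------------------------------
# contrasts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContrastSpec:
    """Named signed-weight combination of task columns.

    GB and NF contrasts average the high-value/novel conditions minus the
    low-value/familiar ones across hemifields; their weights sum to zero.
    """

    name: str
    weights: dict

    @staticmethod
    def gb() -> "ContrastSpec":
        return ContrastSpec(
            "GB",
            {"good_left": 0.5, "good_right": 0.5, "bad_left": -0.5, "bad_right": -0.5},
        )

    @staticmethod
    def nf() -> "ContrastSpec":
        return ContrastSpec(
            "NF",
            {
                "novel_left": 0.5,
                "novel_right": 0.5,
                "familiar_left": -0.5,
                "familiar_right": -0.5,
            },
        )

    @staticmethod
    def visual() -> "ContrastSpec":
        return ContrastSpec("visual", {"probe": 1.0})

    @staticmethod
    def for_scan(scan_type: str) -> "ContrastSpec":
        return ContrastSpec.gb() if scan_type == "GB" else ContrastSpec.nf()


@dataclass
class ContrastMap:
    name: str
    effect: np.ndarray              # beta combination, percent units
    tstat: np.ndarray
    dof: int
    shape: tuple = None

    def effect_volume(self) -> np.ndarray:
        return self.effect.reshape(self.shape) if self.shape else self.effect

    def t_volume(self) -> np.ndarray:
        return self.tstat.reshape(self.shape) if self.shape else self.tstat


def contrast_map(result: GlmResult, spec: ContrastSpec) -> ContrastMap:
    """Linear contrast of betas with its voxelwise t statistic."""
    missing = [c for c in spec.weights if c not in result.columns]
    if missing:
        raise ValueError(
            f"contrast {spec.name!r} references columns absent from this fit: {missing}"
        )
    w = np.zeros(len(result.columns))
    for c, v in spec.weights.items():
        w[result.columns.index(c)] = v
    effect = result.betas @ w
    var = result.sigma2 * float(w @ result.xtx_inv @ w)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var > 0, effect / np.sqrt(var), 0.0)
    return ContrastMap(
        name=spec.name, effect=effect, tstat=t, dof=result.dof, shape=result.shape
    )
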