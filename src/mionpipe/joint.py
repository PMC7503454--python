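"""Joint novelty/value coding summaries.

Three analyses over per-voxel GB (value) and NF (novelty) betas:

* per-region averages over the most visually active voxels (selection by
  the probe-vs-base beta, which is orthogonal to value, novelty and
  hemifield coding);
* classification of voxels against iso-probability contours of the joint
  GB/NF null distribution (bivariate Gaussian fit over all gray-matter
  voxels regardless of significance, Mahalanobis ellipses at the 68% and
  95% levels);
* per-network correlation between canonicalized NF and GB block time
  courses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synth import SimulatedRun

log = logging.getLogger(__name__)


@dataclass
class JointCodingField:
    gb: np.ndarray                  # per-voxel GB beta, percent units
    nf: np.ndarray
    network: np.ndarray             # network id per voxel, 0 = none
    gray: np.ndarray                # gray-matter flag

    def __post_init__(self) -> None:
        self.gb = np.asarray(self.gb, float).ravel()
        self.nf = np.asarray(self.nf, float).ravel()
        self.network = np.asarray(self.network).ravel()
        self.gray = np.asarray(self.gray, bool).ravel()
        if not (len(self.gb) == len(self.nf) == len(self.network) == len(self.gray)):
            raise ValueError("field arrays must share a length")
        if not np.isfinite(self.gb[self.gray]).all() or not np.isfinite(
            self.nf[self.gray]
        ).all():
            raise ValueError("betas must be finite over gray matter")


# ---------------------------------------------------------------------------
# top visually-active voxel averaging
# ---------------------------------------------------------------------------

def top_visual_average(
    gb_betas: np.ndarray,
    nf_betas: np.ndarray,
    visual_betas: np.ndarray,
    labels: np.ndarray,
    n_top: int = 10,
) -> pd.DataFrame:
    """Per-region mean GB/NF betas over the ``n_top`` most visually active
    voxels (ranked only on the visual beta; ties broken by voxel index, so
    the selection never looks at GB or NF values). Regions with fewer than
    ``n_top`` voxels use all of them (logged).
    """
    gb = np.asarray(gb_betas, float).ravel()
    nf = np.asarray(nf_betas, float).ravel()
    vis = np.asarray(visual_betas, float).ravel()
    lab = np.asarray(labels).ravel()
    rows = []
    for r in sorted(int(v) for v in np.unique(lab) if v != 0):
        idx = np.flatnonzero(lab == r)
        if idx.size == 0:       # pragma: no cover - unique() excludes this
            continue
        if idx.size < n_top:
            log.warning("region %d has %d < %d voxels; using all", r, idx.size, n_top)
            sel = idx
        else:
            order = np.argsort(-vis[idx], kind="stable")
            sel = idx[order[:n_top]]
        m = len(sel)
        rows.append(
            {
                "region": r,
                "n_voxels": m,
                "mean_GB": gb[sel].mean(),
                "mean_NF": nf[sel].mean(),
                "sem_GB": gb[sel].std(ddof=1) / np.sqrt(m) if m > 1 else 0.0,
                "sem_NF": nf[sel].std(ddof=1) / np.sqrt(m) if m > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# joint null distribution and contour classification
# ---------------------------------------------------------------------------

@dataclass
class JointNull:
    mean: np.ndarray                # (2,): GB, NF
    cov: np.ndarray                 # (2, 2)

    def mahalanobis_sq(self, gb: np.ndarray, nf: np.ndarray) -> np.ndarray:
        d = np.column_stack([np.ravel(gb), np.ravel(nf)]) - self.mean
        sol = np.linalg.solve(self.cov, d.T)
        return np.einsum("ij,ji->i", d, sol)


@dataclass(frozen=True)
class ContourSpec:
    levels: tuple[float, ...] = (0.68, 0.95)
    model: str = "gaussian"

    def __post_init__(self) -> None:
        lv = self.levels
        if any(not 0 < q < 1 for q in lv) or any(
            lv[i] >= lv[i + 1] for i in range(len(lv) - 1)
        ):
            raise ValueError("levels must be strictly increasing in (0, 1)")
        if self.model not in ("gaussian", "kde"):
            raise ValueError("model must be 'gaussian' or 'kde'")


def fit_joint_null(field: JointCodingField) -> JointNull:
    """Bivariate Gaussian over all gray-matter voxels, significant or not."""
    gb, nf = field.gb[field.gray], field.nf[field.gray]
    if gb.size < 10:
        raise ValueError("need at least 10 gray-matter voxels")
    X = np.column_stack([gb, nf])
    mean = X.mean(axis=0)
    cov = np.cov(X.T)
    if np.linalg.det(cov) <= np.finfo(float).eps * np.trace(cov) ** 2:
        raise ValueError("joint null covariance is singular (data on a line?)")
    return JointNull(mean=mean, cov=cov)


def classify_outside_contour(
    field: JointCodingField,
    null: JointNull,
    spec: ContourSpec = ContourSpec(),
) -> dict:
    """Flag voxels outside each iso-probability contour of the null.

    Under the Gaussian model a voxel lies outside level q iff its squared
    Mahalanobis distance exceeds the chi-square(2) quantile at q. A KDE
    variant thresholds the kernel density at the level enclosing mass q.
    Returns flags per level, per-network outside fractions, and marginal
    GB/NF histograms.
    """
    out_flags: dict[float, np.ndarray] = {}
    if spec.model == "gaussian":
        d2 = null.mahalanobis_sq(field.gb, field.nf)
        for q in spec.levels:
            out_flags[q] = d2 > stats.chi2.ppf(q, df=2)
    else:
        train = np.vstack([field.gb[field.gray], field.nf[field.gray]])
        kde = stats.gaussian_kde(train)
        dens_train = kde(train)
        dens = kde(np.vstack([field.gb, field.nf]))
        for q in spec.levels:
            out_flags[q] = dens < np.quantile(dens_train, 1.0 - q)

    networks = sorted(int(w) for w in np.unique(field.network) if w != 0)
    frac = {
        q: {
            w: float(out_flags[q][field.network == w].mean())
            for w in networks
            if (field.network == w).any()
        }
        for q in spec.levels
    }
    hist_gb = np.histogram(field.gb[field.gray], bins=50)
    hist_nf = np.histogram(field.nf[field.gray], bins=50)
    return {
        "outside": out_flags,
        "network_outside_fraction": frac,
        "marginals": {"GB": hist_gb, "NF": hist_nf},
    }


# ---------------------------------------------------------------------------
# NF/GB time-course correlation
# ---------------------------------------------------------------------------

def plot_joint_field(field: JointCodingField, null: JointNull, path,
                     spec: ContourSpec = ContourSpec()) -> None:
    """Optional scatter of GB vs NF betas with null iso-probability
    ellipses, colored by network; writes SVG/PNG by file extension."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    nets = sorted(int(w) for w in np.unique(field.network))
    for w in nets:
        sel = field.network == w
        ax.scatter(field.gb[sel], field.nf[sel], s=4,
                   label=f"network {w}" if w else "unassigned", alpha=0.5)
    theta = np.linspace(0, 2 * np.pi, 200)
    vals, vecs = np.linalg.eigh(null.cov)
    for q, ls in zip(spec.levels, ("--", ":")):
        r = np.sqrt(stats.chi2.ppf(q, df=2))
        ring = (vecs * np.sqrt(vals)) @ np.vstack([np.cos(theta), np.sin(theta)]) * r
        ax.plot(null.mean[0] + ring[0], null.mean[1] + ring[1], ls, color="k",
                label=f"{int(q * 100)}%")
    ax.set_xlabel("GB beta (% signal)")
    ax.set_ylabel("NF beta (% signal)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


#: canonical probe order used to align runs with different pseudorandom
#: block sequences; "high" = good or novel, "low" = bad or familiar
CANONICAL_ORDER = ("high_left", "high_right", "low_left", "low_right")

_CANON = {
    "good_left": "high_left", "good_right": "high_right",
    "bad_left": "low_left", "bad_right": "low_right",
    "novel_left": "high_left", "novel_right": "high_right",
    "familiar_left": "low_left", "familiar_right": "low_right",
}


def canonical_timecourse(run: SimulatedRun) -> np.ndarray:
    """Block-order-canonicalized voxel time courses for one run.

    Volumes of every block of a given type are averaged in block-relative
    time, and the averages are concatenated as
    [base, high_left, high_right, low_left, low_right]; runs with different
    pseudorandom probe orders become directly comparable.
    """
    design = run.design
    tpb = design.trs_per_block
    data = run.data.reshape(-1, design.n_volumes)
    groups: dict[str, list[np.ndarray]] = {}
    for i, t in enumerate(design.block_types):
        key = "base" if t == "base" else _CANON[t]
        groups.setdefault(key, []).append(data[:, i * tpb : (i + 1) * tpb])
    order = ("base",) + CANONICAL_ORDER
    segs = [np.mean(groups[k], axis=0) for k in order if k in groups]
    return np.concatenate(segs, axis=1)


def nfgb_timecourse_correlation(
    nf_runs: list[SimulatedRun],
    gb_runs: list[SimulatedRun],
    network_labels: np.ndarray,
) -> pd.DataFrame:
    """Per-network mean (+/- s.e.m. over voxels) Pearson correlation between
    the run-averaged canonical NF and GB time courses of each voxel."""
    if not nf_runs or not gb_runs:
        raise ValueError("need at least one run of each scan type")
    shapes = {r.data.shape for r in nf_runs} | {r.data.shape for r in gb_runs}
    if len(shapes) != 1:
        raise ValueError(f"runs disagree on the data grid: {shapes}")
    nf_avg = np.mean([canonical_timecourse(r) for r in nf_runs], axis=0)
    gb_avg = np.mean([canonical_timecourse(r) for r in gb_runs], axis=0)
    if nf_avg.shape != gb_avg.shape:
        raise ValueError("NF and GB canonical courses have mismatched lengths")

    a = nf_avg - nf_avg.mean(axis=1, keepdims=True)
    b = gb_avg - gb_avg.mean(axis=1, keepdims=True)
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where((na > 0) & (nb > 0), (a * b).sum(axis=1) / (na * nb), 0.0)
    r = np.clip(r, -1.0, 1.0)

    lab = np.asarray(network_labels).ravel()
    rows = []
    for w in sorted(int(v) for v in np.unique(lab) if v != 0):
        rv = r[lab == w]
        rows.append(
            {
                "network": w,
                "n_voxels": rv.size,
                "mean_r": rv.mean(),
                "sem_r": rv.std(ddof=1) / np.sqrt(rv.size) if rv.size > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)
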