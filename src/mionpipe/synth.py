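"""Synthetic task and resting-state data with known ground truth.

Emulates the passive-viewing block design used for mapping object novelty
(novel/familiar, "NF") and value (good/bad, "GB") coding in awake macaque
fMRI with the MION contrast agent: 16 alternating base/probe blocks of 30 s
at TR 2.5 s, four pseudorandomized probe types per scan type
([high, low] x [left, right] hemifield), sign-inverted (MION) hemodynamics,
planted per-network percent-signal effects, spatially autocorrelated noise,
and resting covariance generated from a known sparse precision matrix.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster import AcfParams, AcfNoiseFactory

GB_CONDITIONS = ("good_left", "good_right", "bad_left", "bad_right")
NF_CONDITIONS = ("novel_left", "novel_right", "familiar_left", "familiar_right")

#: nuisance trace names: 6 rigid-body motion + 6 derivatives, reward, blinks,
#: eye position (horizontal, vertical and their interaction) = 17 columns
MOTION_COLUMNS = tuple(
    f"motion_{p}" for p in ("tx", "ty", "tz", "rx", "ry", "rz")
) + tuple(f"dmotion_{p}" for p in ("tx", "ty", "tz", "rx", "ry", "rz"))
EVENT_COLUMNS = ("reward", "blinks", "eye_h", "eye_v", "eye_hv")
NUISANCE_COLUMNS = MOTION_COLUMNS + EVENT_COLUMNS


def conditions_for(scan_type: str) -> tuple[str, ...]:
    if scan_type == "GB":
        return GB_CONDITIONS
    if scan_type == "NF":
        return NF_CONDITIONS
    raise ValueError(f"scan_type must be 'GB' or 'NF', got {scan_type!r}")


# ---------------------------------------------------------------------------
# scan design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScanDesign:
    """Block timing of one run: alternating base/probe blocks.

    ``block_types`` lists one label per block: ``"base"`` or a probe
    condition name; probe types are balanced so that every window of four
    consecutive probe blocks contains each of the four types exactly once.
    """

    scan_type: str
    block_types: tuple[str, ...]
    tr_s: float = 2.5
    block_s: float = 30.0
    stim_on_ms: int = 600
    stim_off_ms: int = 200
    n_discard_trs: int = 3

    def __post_init__(self) -> None:
        n_vol = self.n_blocks * self.block_s / self.tr_s
        if abs(n_vol - round(n_vol)) > 1e-9:
            raise ValueError("n_blocks * block_s / tr_s must be an integer")
        types = self.block_types
        if any(t != "base" for t in types[::2]) or any(
            t == "base" for t in types[1::2]
        ):
            raise ValueError("base and probe blocks must strictly alternate")
        probes = [t for t in types if t != "base"]
        conds = conditions_for(self.scan_type)
        # each cycle of four sequential probe blocks shows all four types
        for i in range(0, len(probes), 4):
            window = probes[i : i + 4]
            if sorted(window) != sorted(conds):
                raise ValueError(
                    "every cycle of 4 sequential probe blocks must show all 4 types"
                )

    @property
    def n_blocks(self) -> int:
        return len(self.block_types)

    @property
    def trs_per_block(self) -> int:
        return int(round(self.block_s / self.tr_s))

    @property
    def n_volumes(self) -> int:
        return self.n_blocks * self.trs_per_block

    @property
    def conditions(self) -> tuple[str, ...]:
        return conditions_for(self.scan_type)

    def events(self, excluded_blocks: set[int] | None = None) -> pd.DataFrame:
        """Block-level events table (onset, duration, trial_type, hemifield)."""
        excluded_blocks = excluded_blocks or set()
        rows = []
        for i, t in enumerate(self.block_types):
            hemifield = "n/a"
            if t != "base":
                hemifield = t.rsplit("_", 1)[1]
            rows.append(
                {
                    "onset": i * self.block_s,
                    "duration": self.block_s,
                    "trial_type": t,
                    "hemifield": hemifield,
                    "excluded": i in excluded_blocks,
                }
            )
        return pd.DataFrame(rows)


def make_design(
    scan_type: str,
    seed: int,
    n_cycles: int = 2,
    tr_s: float = 2.5,
    block_s: float = 30.0,
) -> ScanDesign:
    """Pseudorandomized design: per cycle a seeded permutation of the 4 probe
    types, base blocks interleaved before each probe block.
    """
    conds = conditions_for(scan_type)
    rng = np.random.default_rng(seed)
    blocks: list[str] = []
    for _ in range(n_cycles):
        order = rng.permutation(len(conds))
        for j in order:
            blocks.append("base")
            blocks.append(conds[j])
    return ScanDesign(
        scan_type=scan_type, block_types=tuple(blocks), tr_s=tr_s, block_s=block_s
    )


# ---------------------------------------------------------------------------
# MION impulse response
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MionKernel:
    """Sign-inverted hemodynamic impulse response for the MION contrast agent.

    Activation increases cerebral blood volume, which *decreases* the
    measured T2* signal, so the kernel peak is negative. Normalized so that
    a sustained unit boxcar input asymptotes to -1.
    """

    times: np.ndarray
    amplitudes: np.ndarray
    dt: float

    def convolve(self, x: np.ndarray) -> np.ndarray:
        """Causal convolution of a series sampled at ``dt``; same length."""
        full = np.convolve(np.asarray(x, float), self.amplitudes) * self.dt
        return full[: len(x)]


def mion_irf(
    peak_delay_s: float = 10.0,
    undershoot_ratio: float = 0.0,
    dt: float = 0.1,
    duration_s: float = 90.0,
    shape: float = 3.0,
) -> MionKernel:
    """Gamma-variate MION impulse response.

    ``peak_delay_s`` places the (negative) peak; ``undershoot_ratio`` mixes
    in a delayed positive lobe of that relative area (default none — MION
    responses are slow and monophasic).
    """
    if peak_delay_s <= 0:
        raise ValueError("peak_delay_s must be positive")
    if not 0 <= undershoot_ratio < 1:
        raise ValueError("undershoot_ratio must be in [0, 1)")
    t = np.arange(0.0, duration_s, dt)
    theta = peak_delay_s / (shape - 1.0)
    g = t ** (shape - 1.0) * np.exp(-t / theta)
    g /= g.sum() * dt
    h = -g
    if undershoot_ratio > 0:
        theta2 = 2.0 * theta
        g2 = t ** (shape - 1.0) * np.exp(-t / theta2)
        g2 /= g2.sum() * dt
        h = -(g - undershoot_ratio * g2) / (1.0 - undershoot_ratio)
    return MionKernel(times=t, amplitudes=h, dt=dt)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Planted statistical structure for a simulated subject.

    ``effect_pct`` maps (network_id, contrast, hemifield) -> percent-signal
    effect, contrast in {"GB", "NF", "visual"}; condition-level effects are
    derived so that the GB (NF) contrast of GLM betas equals the planted GB
    (NF) value and the probe-vs-base response equals the visual value.
    """

    region_labels: np.ndarray
    network_of_region: dict[int, int]
    effect_pct: dict[tuple[int, str, str], float]
    rest_precision: np.ndarray
    noise_acf: AcfParams = field(default_factory=lambda: AcfParams(0.97, 1.10, 9.01))
    tsnr: float = 25.0
    baseline: float = 1000.0
    nuisance_amp_pct: float = 0.01

    def __post_init__(self) -> None:
        P = np.asarray(self.rest_precision, float)
        if not np.allclose(P, P.T, atol=1e-10):
            raise ValueError("rest_precision must be symmetric")
        if np.linalg.eigvalsh(P).min() <= 0:
            raise ValueError("rest_precision must be positive definite")

    @property
    def regions(self) -> list[int]:
        return sorted(self.network_of_region)

    def network_labels(self) -> np.ndarray:
        """Voxelwise network-id volume (0 outside any region)."""
        out = np.zeros_like(self.region_labels)
        for r, w in self.network_of_region.items():
            out[self.region_labels == r] = w
        return out

    def condition_effect(self, condition: str, network: int) -> float:
        """Percent effect of one probe condition in one network."""
        level, hemifield = condition.rsplit("_", 1)
        contrast = "GB" if level in ("good", "bad") else "NF"
        sign = 1.0 if level in ("good", "novel") else -1.0
        vis = self.effect_pct.get((network, "visual", hemifield), 0.0)
        diff = self.effect_pct.get((network, contrast, hemifield), 0.0)
        return vis + sign * diff / 2.0


def planted_precision(
    n_networks: int = 4,
    regions_per_network: int = 6,
    within: float = 0.15,
    between: float = 0.08,
) -> tuple[np.ndarray, dict[int, int]]:
    """Sparse SPD precision over regions: dense positive partial correlations
    within each network, a single weak bridge between consecutive networks so
    the graph is connected. Returns (precision, region -> network map).
    """
    p = n_networks * regions_per_network
    P = np.eye(p)
    network_of = {}
    for w in range(n_networks):
        idx = range(w * regions_per_network, (w + 1) * regions_per_network)
        for i in idx:
            network_of[i + 1] = w + 1
            for j in idx:
                if i != j:
                    P[i, j] = -within
    for w in range(n_networks):
        i = w * regions_per_network + (regions_per_network - 1)
        j = ((w + 1) % n_networks) * regions_per_network
        P[i, j] = P[j, i] = -between
    if np.linalg.eigvalsh(P).min() <= 0:  # pragma: no cover - guarded by defaults
        raise ValueError("planted precision not positive definite; reduce weights")
    return P, network_of


def make_ground_truth(
    shape: tuple[int, int, int] = (24, 24, 16),
    n_networks: int = 4,
    regions_per_network: int = 6,
    gb_effect: float = 0.1,
    nf_effect: float = 0.1,
    visual_effect: float = 0.2,
    tsnr: float = 25.0,
    acf: AcfParams | None = None,
) -> GroundTruth:
    """Default desk-scale ground truth: regions tile the volume as equal
    slabs along x, networks group consecutive regions; effects planted with
    a GB-coding network 1, an NF-coding network 2, a joint network 3 and a
    silent network 4 (when 4 networks are requested).
    """
    n_regions = n_networks * regions_per_network
    P, network_of = planted_precision(n_networks, regions_per_network)
    labels = np.zeros(shape, dtype=np.int32)
    nx = shape[0]
    edges = np.linspace(0, nx, n_regions + 1).astype(int)
    for r in range(n_regions):
        labels[edges[r] : edges[r + 1], :, :] = r + 1
    effect: dict[tuple[int, str, str], float] = {}
    coding = {1: ("GB",), 2: ("NF",), 3: ("GB", "NF")}
    for w in range(1, n_networks + 1):
        for hemi in ("left", "right"):
            effect[(w, "visual", hemi)] = visual_effect
            for contrast in coding.get(w, ()):
                effect[(w, contrast, hemi)] = gb_effect if contrast == "GB" else nf_effect
    return GroundTruth(
        region_labels=labels,
        network_of_region=network_of,
        effect_pct=effect,
        rest_precision=P,
        noise_acf=acf or AcfParams(0.97, 1.10, 9.01),
        tsnr=tsnr,
    )


# ---------------------------------------------------------------------------
# task-run simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedRun:
    data: np.ndarray                # (x, y, z, t) raw signal
    events: pd.DataFrame
    nuisance: pd.DataFrame          # one row per volume, 17 columns
    design: ScanDesign
    truth: GroundTruth
    seed: int


def _nuisance_traces(n_vol: int, rng: np.random.Generator) -> pd.DataFrame:
    """17 nuisance traces: motion as smoothed random walks plus derivatives,
    sparse reward/blink impulses, slowly wandering eye position."""
    cols = {}
    motion = {}
    for name in MOTION_COLUMNS[:6]:
        w = np.cumsum(rng.normal(0, 0.02, n_vol))
        motion[name] = w
        cols[name] = w
    for base, name in zip(MOTION_COLUMNS[:6], MOTION_COLUMNS[6:]):
        d = np.diff(motion[base], prepend=motion[base][0])
        cols[name] = d
    cols["reward"] = (rng.random(n_vol) < 0.2).astype(float)
    cols["blinks"] = (rng.random(n_vol) < 0.1).astype(float)
    eh = np.cumsum(rng.normal(0, 0.1, n_vol))
    ev = np.cumsum(rng.normal(0, 0.1, n_vol))
    cols["eye_h"] = eh
    cols["eye_v"] = ev
    cols["eye_hv"] = eh * ev
    df = pd.DataFrame(cols, columns=list(NUISANCE_COLUMNS))
    # degenerate (all-zero) impulse traces break the GLM contract; make sure
    # at least one event is present
    for name in ("reward", "blinks"):
        if not df[name].any():
            df.loc[rng.integers(0, n_vol), name] = 1.0
    return df


def convolve_trace_tr(trace: np.ndarray, kernel: MionKernel, tr_s: float) -> np.ndarray:
    """Convolve a TR-sampled trace with the MION kernel decimated to TR.

    Used for the non-motion nuisance regressors, which are only observed at
    volume resolution; the simulator and the GLM share this exact operation.
    """
    step = max(1, int(round(tr_s / kernel.dt)))
    k = kernel.amplitudes[::step] * tr_s
    return np.convolve(np.asarray(trace, float), k)[: len(trace)]


def condition_regressors(
    design: ScanDesign, kernel: MionKernel, events: pd.DataFrame | None = None
) -> pd.DataFrame:
    """MION-convolved boxcar regressor per probe condition, sampled at TR.

    Built at the kernel's fine time step then decimated to volume times.
    """
    ev = events if events is not None else design.events()
    n_fine = int(round(design.n_volumes * design.tr_s / kernel.dt))
    t_fine = np.arange(n_fine) * kernel.dt
    cols = {}
    for cond in design.conditions:
        box = np.zeros(n_fine)
        for _, row in ev[ev.trial_type == cond].iterrows():
            on = (t_fine >= row.onset) & (t_fine < row.onset + row.duration)
            box[on] = 1.0
        conv = kernel.convolve(box)
        vol_idx = (np.arange(design.n_volumes) * design.tr_s / kernel.dt).astype(int)
        cols[cond] = conv[vol_idx]
    return pd.DataFrame(cols)


def simulate_task_run(
    design: ScanDesign,
    truth: GroundTruth,
    seed: int,
    kernel: MionKernel | None = None,
    noise: bool = True,
    exclude_rate: float = 0.0,
) -> SimulatedRun:
    """Simulate one 4D task run.

    Signal model per voxel: baseline * (1 + sum_c boxcar_c * effect_c/100
    convolved with the MION kernel) + nuisance contributions + spatially
    ACF-correlated noise scaled to the target temporal SNR.
    """
    if truth.region_labels.ndim != 3:
        raise ValueError("region_labels must be a 3D volume")
    kernel = kernel or mion_irf()
    rng = np.random.default_rng(seed)
    shape = truth.region_labels.shape
    n_vol = design.n_volumes

    excluded = set()
    if exclude_rate > 0:
        probe_idx = [i for i, t in enumerate(design.block_types) if t != "base"]
        excluded = {i for i in probe_idx if rng.random() < exclude_rate}
    events = design.events(excluded)

    regs = condition_regressors(design, kernel, events)
    net_vol = truth.network_labels()
    pct = np.zeros(shape + (n_vol,), dtype=np.float64)
    for w in sorted(set(truth.network_of_region.values())):
        vox = net_vol == w
        if not vox.any():
            continue
        series = np.zeros(n_vol)
        for cond in design.conditions:
            series += regs[cond].to_numpy() * truth.condition_effect(cond, w)
        pct[vox, :] = series

    nuis = _nuisance_traces(n_vol, rng)
    if truth.nuisance_amp_pct:
        load = rng.normal(0.0, 1.0, len(NUISANCE_COLUMNS))
        contrib = np.zeros(n_vol)
        for k, name in enumerate(NUISANCE_COLUMNS):
            trace = nuis[name].to_numpy()
            if name not in MOTION_COLUMNS:
                # non-motion nuisance enters through the hemodynamics
                trace = convolve_trace_tr(trace, kernel, design.tr_s)
            s = trace.std()
            if s > 0:
                contrib = contrib + load[k] * truth.nuisance_amp_pct * trace / s
        pct += contrib  # same loading everywhere: keeps the model identifiable

    # plant effects as deviations from the voxel temporal mean so that betas
    # estimated on percent-change-from-mean data equal the planted values
    pct -= pct.mean(axis=-1, keepdims=True)
    data = truth.baseline * (1.0 + pct / 100.0)
    if noise:
        factory = AcfNoiseFactory(truth.noise_acf, shape)
        sigma = truth.baseline / truth.tsnr
        fields = factory.simulate_many(n_vol, rng) * sigma
        data = data + np.moveaxis(fields, 0, -1)
    return SimulatedRun(
        data=data, events=events, nuisance=nuis, design=design, truth=truth, seed=seed
    )


# ---------------------------------------------------------------------------
# resting-state simulation
# ---------------------------------------------------------------------------

def simulate_rest(
    truth: GroundTruth,
    n_volumes: int,
    seed: int,
    confound_amp: float = 0.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Draw a region x time matrix of zero-mean Gaussians with covariance
    inverse(rest_precision); optionally add shared white-matter/ventricle
    style confound traces with known loadings.

    Returns (matrix, confounds) where confounds has columns
    ``white_matter`` and ``ventricle`` (zero if confound_amp == 0).
    """
    P = np.asarray(truth.rest_precision, float)
    p = P.shape[0]
    if n_volumes <= p:
        raise ValueError("n_volumes must exceed the number of regions")
    vals = np.linalg.eigvalsh(P)
    if vals.min() <= 0:
        raise ValueError("rest_precision must be positive definite")
    rng = np.random.default_rng(seed)
    cov = np.linalg.inv(P)
    L = np.linalg.cholesky(cov)
    X = L @ rng.standard_normal((p, n_volumes))
    conf = pd.DataFrame(
        {"white_matter": np.zeros(n_volumes), "ventricle": np.zeros(n_volumes)}
    )
    if confound_amp > 0:
        wm = rng.standard_normal(n_volumes)
        vent = rng.standard_normal(n_volumes)
        conf["white_matter"] = wm
        conf["ventricle"] = vent
        load = rng.normal(0.0, 1.0, (p, 2))
        X = X + confound_amp * (np.outer(load[:, 0], wm) + np.outer(load[:, 1], vent))
    return X, conf
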