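"""Synthetic embryoid-body cohorts: reporter kinetics, point clouds, qPCR panels.

The generator is the forward model of the whole analysis. Each simulated EB
gets latent kinetic truth — an onset time, an onset-to-peak interval, an
amplitude coupled to EB size — realized as an impulse count curve with
counting noise, optionally as a 3D point-cloud movie (a GFP cap spreading
from a single locus over a spherical shell, plus plate/agar clutter), and
as a single-EB qPCR CT panel whose genes trend linearly in developmental
age. Default parameters reproduce the within-experiment statistics of the
baseline experiment: onset 83.3 ± 3.7 h after seeding, onset-to-peak
12.8 ± 2.2 h, EB radius 113 ± 19 µm (span 81–176 µm), amplitudes of a few
thousand segmentation points for aggregates of ~500 cells. Perturbation
presets emulate canonical-Wnt (CHIR) and Bmp4 treatments: early onset
(50 h vs 70 h control in the perturbation experiment), smaller EBs under
long CHIR, and expression shifts including Wnt3 down-regulation.

Every latent is recorded in a truth structure so downstream stages can be
tested for recovery; with the seed fixed the outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .kinetics import (
    DEFAULT_ONSET_THRESHOLD,
    EBTimeSeries,
    ImpulseParams,
    detect_onset,
    detect_peak,
    impulse_value,
)
from .pointcloud import PointCloudFrame
from .qpcrnorm import ExpressionPanel

__all__ = [
    "CohortConfig",
    "GeneSpec",
    "NoiseModel",
    "Cohort",
    "impulse_params_for_events",
    "gen_impulse_series",
    "gen_point_cloud_series",
    "gen_expression_panel",
    "gen_cohort",
    "gen_mode_panel",
    "draw_radii",
    "perturbation_preset",
    "default_gene_panel",
    "PERTURBATIONS",
]

PERTURBATIONS = ("control", "chir_long", "chir_short_early", "chir_short_late", "bmp4")


@dataclass(frozen=True)
class NoiseModel:
    """Counting-noise model for the impulse series.

    kind: 'poisson' (variance = mean, the default for counts of segmented
    objects), 'gaussian' (additive, sd = scale), or 'none' (exact curve).
    """

    kind: str = "poisson"
    scale: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("poisson", "gaussian", "none"):
            raise ValueError(f"unknown noise kind {self.kind!r}")


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one simulated experiment of co-seeded EBs.

    Defaults are the baseline-experiment values: onset distribution
    83.3 ± 3.7 h, onset-to-peak 12.8 ± 2.2 h, radii 113 ± 19 µm truncated to
    the observed 81–176 µm span, frames every 1.5 h.
    """

    n_ebs: int = 50
    onset_mean: float = 83.3  # hours after seeding
    onset_sd: float = 3.7
    onset_to_peak_mean: float = 12.8  # hours
    onset_to_peak_sd: float = 2.2
    radius_mean: float = 113.0  # µm
    radius_sd: float = 19.0
    radius_bounds: tuple[float, float] = (81.0, 176.0)
    amplitude_scale: float = 3000.0  # peak segmentation points
    amplitude_sd: float = 450.0
    frame_interval: float = 1.5  # hours (imaging cadence 1-2 h)
    t_start: float = 60.0
    t_end: float = 120.0
    noise_model: NoiseModel = NoiseModel("poisson")
    clutter_rate: float = 30.0  # clutter points per frame
    missing_rate: float = 0.0  # fraction of CT cells dropped (failed reactions)
    harvest_h: float | None = None  # default: t_end
    perturbation: str = "control"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.onset_sd < 0 or self.radius_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.radius_bounds[0] >= self.radius_bounds[1]:
            raise ValueError("radius_bounds must be an increasing pair")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.t_start >= self.t_end:
            raise ValueError("t_start must precede t_end")
        if self.perturbation not in PERTURBATIONS:
            raise ValueError(f"unknown perturbation {self.perturbation!r}")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.t_start, self.t_end + 1e-9, self.frame_interval)


def perturbation_preset(name: str, **overrides) -> CohortConfig:
    """Config preset for the signaling-perturbation experiment.

    In that experiment the matched control shows onset around 70 h, while
    early canonical-Wnt activation (CHIR 24-72 h) or Bmp4 shift it to about
    50 h; long CHIR also yields smaller EBs. Short CHIR pulses perturb
    expression only, leaving the kinetics at control values.
    """
    base = dict(perturbation=name, onset_mean=70.0, t_start=40.0, t_end=100.0)
    if name in ("chir_long", "bmp4"):
        base.update(onset_mean=50.0, t_start=30.0, t_end=85.0)
    if name == "chir_long":
        base.update(radius_mean=85.0, radius_bounds=(60.0, 150.0))
    base.update(overrides)
    return CohortConfig(**base)


@dataclass(frozen=True)
class GeneSpec:
    """Linear-in-DevA expression model for one gene, in −ΔΔCT units.

    The emitted level for an EB with developmental age ``d`` in group ``g``
    is ``intercept + slope_devA * d + perturbation_shifts.get(g, 0) + noise``.
    Housekeeping genes have slope 0 and small noise and are flagged so they
    can serve as normalizers.
    """

    name: str
    intercept: float = 0.0
    slope_devA: float = 0.0  # −ΔΔCT units per hour
    noise_sd: float = 0.5
    perturbation_shifts: dict = field(default_factory=dict)
    wnt3_mode: str = "none"
    housekeeping: bool = False
    ct_base: float = 8.0  # cycles above the housekeeping mean at −ΔΔCT = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.housekeeping and self.slope_devA != 0:
            raise ValueError("housekeeping genes must have slope_devA = 0")


def default_gene_panel() -> list[GeneSpec]:
    """A compact panel echoing the measured one: two stable housekeeping
    genes, primitive-streak genes falling with DevA, late-mesoderm genes
    rising, flat genes, and Wnt3 with CHIR-induced down-regulation."""
    chir_dn = {"chir_long": -4.0, "chir_short_early": -2.5, "chir_short_late": -2.5}
    return [
        GeneSpec("Rock2", housekeeping=True, noise_sd=0.12, ct_base=14.0),
        GeneSpec("Ywhaz", housekeeping=True, noise_sd=0.12, ct_base=13.5),
        GeneSpec("T", intercept=2.0, slope_devA=-0.25, noise_sd=0.8,
                 perturbation_shifts={"chir_long": 3.0, "chir_short_early": 2.0,
                                      "chir_short_late": 2.0}),
        GeneSpec("Otx2", intercept=1.5, slope_devA=-0.20, noise_sd=0.7,
                 perturbation_shifts={"chir_long": -2.5, "bmp4": -2.0}),
        GeneSpec("Eomes", intercept=1.2, slope_devA=-0.18, noise_sd=0.8,
                 perturbation_shifts={"chir_long": -2.0, "bmp4": -1.5}),
        GeneSpec("Mixl1", intercept=1.0, slope_devA=-0.22, noise_sd=0.8),
        GeneSpec("Gata4", intercept=-1.0, slope_devA=0.20, noise_sd=0.8,
                 perturbation_shifts={"chir_long": -1.5}),
        GeneSpec("Gata6", intercept=-0.8, slope_devA=0.18, noise_sd=0.8),
        GeneSpec("Bmp4", intercept=-0.5, slope_devA=0.15, noise_sd=0.7),
        GeneSpec("Lmo2", intercept=-0.6, slope_devA=0.10, noise_sd=0.7,
                 perturbation_shifts={"chir_long": 2.5, "chir_short_early": 1.5,
                                      "chir_short_late": 1.5}),
        GeneSpec("Pax6", intercept=0.0, slope_devA=0.0, noise_sd=0.8),
        GeneSpec("Cby1", intercept=0.3, slope_devA=0.0, noise_sd=0.7),
        GeneSpec("Wnt3", intercept=1.0, slope_devA=-0.15, noise_sd=0.6,
                 perturbation_shifts=chir_dn),
    ]


# ---------------------------------------------------------------------------
# kinetic parameter construction


def impulse_params_for_events(
    onset: float,
    onset_to_peak: float,
    A: float,
    beta1: float,
    beta2: float,
    threshold: float = DEFAULT_ONSET_THRESHOLD,
) -> ImpulseParams:
    """Impulse parameters whose detected onset and onset-to-peak interval
    equal the requested values exactly (to root-finder tolerance).

    The half-peak gap t2 − t1 controls the onset-to-peak interval
    monotonically; it is solved by bisection, after which the curve is
    time-shifted so the threshold crossing lands on ``onset``.
    """
    if A <= threshold:
        raise ValueError("amplitude must exceed the onset threshold")
    if onset_to_peak <= 0:
        raise ValueError("onset_to_peak must be positive")

    def interval(gap: float) -> float | None:
        p = ImpulseParams(A, beta1, beta2, 0.0, gap)
        on = detect_onset(p, threshold)
        if on is None:
            return None
        return detect_peak(p) - on

    g_lo, g_hi = 0.05, 8.0
    while True:
        iv = interval(g_hi)
        if iv is not None and iv >= onset_to_peak:
            break
        g_hi *= 2.0
        if g_hi > 4096:  # pragma: no cover
            raise RuntimeError("failed to bracket onset-to-peak interval")
    for _ in range(200):
        mid = 0.5 * (g_lo + g_hi)
        iv = interval(mid)
        if iv is None or iv < onset_to_peak:
            g_lo = mid
        else:
            g_hi = mid
        if g_hi - g_lo < 1e-8:
            break
    gap = g_hi
    p0 = ImpulseParams(A, beta1, beta2, 0.0, gap)
    shift = onset - detect_onset(p0, threshold)
    return ImpulseParams(A, beta1, beta2, shift, shift + gap)


def gen_impulse_series(
    params: ImpulseParams,
    times: np.ndarray,
    noise_model: NoiseModel = NoiseModel("none"),
    rng: np.random.Generator | int | None = None,
    eb_id: str = "eb",
) -> EBTimeSeries:
    """Realize one count curve from the impulse model under counting noise.

    Noisy counts are rounded and clipped at zero; with ``kind='none'`` the
    exact model values are returned.
    """
    times = np.asarray(times, dtype=float)
    if times.size and np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    rng = np.random.default_rng(rng)
    model = impulse_value(params, times)
    if noise_model.kind == "none":
        counts = model
    elif noise_model.kind == "poisson":
        counts = rng.poisson(model).astype(float)
    else:
        counts = np.maximum(0.0, np.round(model + rng.normal(0.0, noise_model.scale, times.size)))
    return EBTimeSeries(eb_id=eb_id, times=times, counts=counts)


# ---------------------------------------------------------------------------
# point clouds


def _rotation_to(locus: np.ndarray) -> np.ndarray:
    """Rotation matrix taking +z to the unit vector ``locus``."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, locus)
    c = float(np.dot(z, locus))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def gen_point_cloud_series(
    radius: float,
    onset_locus: np.ndarray,
    params: ImpulseParams,
    times: np.ndarray,
    clutter_rate: float = 0.0,
    rng: np.random.Generator | int | None = None,
    cap_capacity: float | None = None,
    shell_jitter: float = 2.0,
) -> list[PointCloudFrame]:
    """GFP point-cloud movie: a contiguous cap spreading from a single locus.

    At each frame, round(N(t)) GFP points are drawn uniformly on a spherical
    cap centered on ``onset_locus`` whose area fraction is N(t)/cap_capacity
    (capacity defaults to the amplitude A, so a full-amplitude signal covers
    the whole shell, angular extent π). The cap therefore grows during the
    rise and recedes back toward the locus during the decline, as observed.
    Clutter points (plate and agar) are placed strictly outside the EB
    sphere: a uniform background plus a sparse far cluster.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    locus = np.asarray(onset_locus, dtype=float)
    locus = locus / np.linalg.norm(locus)
    rng = np.random.default_rng(rng)
    cap = float(cap_capacity if cap_capacity is not None else params.A)
    rot = _rotation_to(locus)
    frames: list[PointCloudFrame] = []
    for t in np.asarray(times, dtype=float):
        n = int(round(float(impulse_value(params, t))))
        frac = min(1.0, n / cap) if cap > 0 else 0.0
        pts = np.empty((0, 3))
        inten = np.empty(0)
        if n > 0:
            cos_theta = rng.uniform(1.0 - 2.0 * frac, 1.0, size=n)
            phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
            sin_theta = np.sqrt(np.maximum(0.0, 1.0 - cos_theta**2))
            dirs = np.column_stack(
                [sin_theta * np.cos(phi), sin_theta * np.sin(phi), cos_theta]
            )
            r = radius + rng.normal(0.0, shell_jitter, size=n)
            pts = (dirs @ rot.T) * r[:, None]
            inten = rng.gamma(4.0, 25.0, size=n)
        if clutter_rate > 0:
            n_bg = rng.poisson(clutter_rate)
            bg = []
            while len(bg) < n_bg:
                cand = rng.uniform(-2.5 * radius, 2.5 * radius, size=(n_bg, 3))
                keep = np.linalg.norm(cand, axis=1) > 1.2 * radius
                bg.extend(cand[keep].tolist())
            bg = np.array(bg[:n_bg]).reshape(-1, 3)
            n_far = rng.poisson(clutter_rate / 4.0)
            far = rng.normal(0.0, 12.0, size=(n_far, 3)) + np.array(
                [0.0, 0.0, -2.2 * radius]
            )
            clutter = np.vstack([bg, far])
            pts = np.vstack([pts, clutter])
            inten = np.concatenate([inten, rng.gamma(2.0, 10.0, size=len(clutter))])
        frames.append(PointCloudFrame(time=float(t), points=pts, intensities=inten))
    return frames


# ---------------------------------------------------------------------------
# expression panels


def _emit_ct(
    neg_ddct: pd.DataFrame,
    metadata: pd.DataFrame,
    hk_specs: list[GeneSpec],
    rng: np.random.Generator,
    missing_rate: float = 0.0,
    ct_base: dict[str, float] | None = None,
) -> ExpressionPanel:
    """Invert the −ΔΔCT transform: emit raw CT values whose normalization
    (against the housekeeping mean and the control-group median) recovers
    ``neg_ddct`` up to gene-wise control-median centering.

    A per-EB loading offset (cell-number differences) is added to every
    gene's CT; it cancels in the housekeeping-normalized ΔCT.
    """
    ebs = list(neg_ddct.columns)
    loading = rng.normal(0.0, 0.35, size=len(ebs))
    rows: dict[str, np.ndarray] = {}
    hk_cts = []
    for spec in hk_specs:
        ct = spec.ct_base + loading + rng.normal(0.0, spec.noise_sd, size=len(ebs))
        rows[spec.name] = ct
        hk_cts.append(ct)
    hk_mean = np.mean(hk_cts, axis=0)
    base = ct_base or {}
    for gene in neg_ddct.index:
        b = base.get(gene, 8.0)
        rows[gene] = hk_mean + b - neg_ddct.loc[gene].to_numpy()
    ct = pd.DataFrame(rows, index=ebs).T
    ct = np.minimum(ct, 30.0)  # 30 amplification cycles cap
    if missing_rate > 0:
        target = [g for g in ct.index if g not in {s.name for s in hk_specs}]
        mask = rng.random((len(target), len(ebs))) < missing_rate
        sub = ct.loc[target].to_numpy()
        sub[mask] = np.nan
        ct.loc[target] = sub
    return ExpressionPanel(ct=ct, metadata=metadata.copy())


def gen_expression_panel(
    devA_per_eb: np.ndarray,
    gene_specs: list[GeneSpec],
    groups: list[str] | None = None,
    rng: np.random.Generator | int | None = None,
    missing_rate: float = 0.0,
    harvest_h: np.ndarray | None = None,
    reference_group: str = "control",
) -> tuple[ExpressionPanel, pd.DataFrame]:
    """Single-EB CT panel with linear-in-DevA gene trends.

    Returns the CT panel plus the truth table of expected −ΔΔCT values —
    the generated levels centered on the reference-group median, which is
    exactly what the normalization stage recovers when fed the designated
    housekeeping normalizers.
    """
    devA = np.asarray(devA_per_eb, dtype=float)
    n = devA.size
    if n == 0:
        raise ValueError("empty cohort")
    groups = list(groups) if groups is not None else ["control"] * n
    if len(groups) != n:
        raise ValueError("one group label per EB required")
    names = [s.name for s in gene_specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate gene names")
    rng = np.random.default_rng(rng)
    hk = [s for s in gene_specs if s.housekeeping]
    meas = [s for s in gene_specs if not s.housekeeping]
    ebs = [f"EB{i:03d}" for i in range(n)]
    vals = {}
    for s in meas:
        shift = np.array([s.perturbation_shifts.get(g, 0.0) for g in groups])
        eps = rng.normal(0.0, s.noise_sd, size=n) if s.noise_sd > 0 else 0.0
        vals[s.name] = s.intercept + s.slope_devA * devA + shift + eps
    neg = pd.DataFrame(vals, index=ebs).T
    metadata = pd.DataFrame(
        {
            "harvest_h": harvest_h if harvest_h is not None else np.full(n, np.nan),
            "group": groups,
            "devA_h": devA,
        },
        index=ebs,
    )
    ctrl = [e for e, g in zip(ebs, groups) if g == reference_group] or ebs
    truth = neg.sub(neg[ctrl].median(axis=1), axis=0)
    panel = _emit_ct(neg, metadata, hk, rng, missing_rate,
                     ct_base={s.name: s.ct_base for s in meas})
    return panel, truth


# ---------------------------------------------------------------------------
# full cohort


def draw_radii(config: CohortConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """EB radii from a truncated normal calibrated to the reported moments.

    The reported radius mean/sd describe the observed (already truncated)
    data, so the parent location is solved such that the truncated
    distribution's mean equals ``radius_mean`` (asymmetric bounds otherwise
    shift it upward).
    """
    lo, hi = config.radius_bounds
    sd = config.radius_sd

    def trunc_mean(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return float(stats.truncnorm.mean(a, b, loc=loc, scale=sd))

    loc = optimize.brentq(
        lambda m: trunc_mean(m) - config.radius_mean, lo - 3 * sd, hi + 3 * sd
    )
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return stats.truncnorm.rvs(a, b, loc=loc, scale=sd, size=n, random_state=rng)


@dataclass
class Cohort:
    """One simulated experiment: count curves, optional point-cloud movies,
    a CT expression panel, and the latent truth behind all of them."""

    config: CohortConfig
    series: list[EBTimeSeries]
    clouds: dict[str, list[PointCloudFrame]]
    panel: ExpressionPanel
    truth: dict


def gen_cohort(
    config: CohortConfig,
    gene_specs: list[GeneSpec] | None = None,
    n_clouds: int = 0,
) -> Cohort:
    """Generate a full synthetic experiment from one config.

    Latents per EB: radius (truncated normal, independent of timing),
    onset (normal), onset-to-peak (normal, floored at 3 h), amplitude
    A = min(A_free, c·R³) with c tuned so only EBs below ~100 µm are
    amplitude-limited by their size. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    gene_specs = gene_specs if gene_specs is not None else default_gene_panel()
    n = config.n_ebs
    radii = draw_radii(config, n, rng)
    onsets = rng.normal(config.onset_mean, config.onset_sd, size=n)
    o2p = np.maximum(3.0, rng.normal(config.onset_to_peak_mean, config.onset_to_peak_sd, size=n))
    a_free = np.maximum(
        2.5 * DEFAULT_ONSET_THRESHOLD,
        rng.normal(config.amplitude_scale, config.amplitude_sd, size=n),
    )
    c_amp = config.amplitude_scale / 100.0**3  # size cap bites below ~100 µm
    amps = np.minimum(a_free, c_amp * radii**3)
    # rise rate calibrated so the 300-600 point crossing window stays narrow
    # (analytic spread ~ ln(2·(A-300)/(A-600))/beta1 < 1.5 h), matching the
    # observed robustness of onset statistics to the threshold choice
    beta1 = np.exp(rng.normal(np.log(0.65), 0.12, size=n))
    beta2 = np.exp(rng.normal(np.log(0.3), 0.12, size=n))

    times = config.times
    harvest = config.harvest_h if config.harvest_h is not None else config.t_end
    series: list[EBTimeSeries] = []
    clouds: dict[str, list[PointCloudFrame]] = {}
    params_list: list[ImpulseParams] = []
    for i in range(n):
        p = impulse_params_for_events(onsets[i], o2p[i], amps[i], beta1[i], beta2[i])
        params_list.append(p)
        eb_id = f"EB{i:03d}"
        s = gen_impulse_series(p, times, config.noise_model, rng, eb_id=eb_id)
        s.radius_pre_onset = float(radii[i])
        series.append(s)
        if i < n_clouds:
            locus = rng.normal(size=3)
            clouds[eb_id] = gen_point_cloud_series(
                radii[i], locus, p, times, config.clutter_rate, rng
            )
    devA = harvest - onsets
    panel, neg_truth = gen_expression_panel(
        devA,
        gene_specs,
        groups=[config.perturbation] * n,
        rng=rng,
        missing_rate=config.missing_rate,
        harvest_h=np.full(n, float(harvest)),
        reference_group=config.perturbation,
    )
    truth = {
        "onset_h": onsets,
        "onset_to_peak_h": o2p,
        "peak_h": onsets + o2p,
        "devA_h": devA,
        "radius_um": radii,
        "amplitude": amps,
        "params": params_list,
        "group": [config.perturbation] * n,
        "neg_ddct": neg_truth,
        "gene_modes": {s.name: s.wnt3_mode for s in gene_specs},
    }
    return Cohort(config=config, series=series, clouds=clouds, panel=panel, truth=truth)


# ---------------------------------------------------------------------------
# Wnt3-dependency mode panel


_MODE_NAMES = (
    "canonical_regulation",
    "trend_continuation",
    "decoupled_parallel",
    "indirect_long_term_only",
    "not_correlated",
)

# Wnt3 −ΔΔCT shift per CHIR group (pathway activation represses the ligand)
_WNT3_SHIFT = {"chir_short_early": -2.5, "chir_short_late": -2.5, "chir_long": -4.0}


def gen_mode_panel(
    genes_per_mode: int = 5,
    n_per_group: int = 12,
    rng: np.random.Generator | int | None = None,
    modes: tuple[str, ...] = _MODE_NAMES,
    as_ct: bool = False,
) -> tuple[ExpressionPanel | pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Panel of genes with designed Wnt3-dependency modes under CHIR groups.

    Wnt3 declines with developmental age and is down-regulated by every
    CHIR treatment. Mode templates (all effects ≥ 3 control SDs):

    - canonical_regulation: responds to pathway activity, so CHIR shifts it
      off the control gene-vs-Wnt3 trend (e.g. up while Wnt3 drops).
    - trend_continuation: tracks the realized Wnt3 level, sliding along the
      control trend to its low-Wnt3 end.
    - decoupled_parallel: co-varies with Wnt3 only through shared timing;
      CHIR leaves its expression at control levels.
    - indirect_long_term_only: shifted by the long treatment only.
    - not_correlated: independent of Wnt3.

    Returns (panel, metadata, mode truth). With ``as_ct`` the panel is
    emitted as raw CT via housekeeping inversion; otherwise the −ΔΔCT
    matrix is returned directly.
    """
    rng = np.random.default_rng(rng)
    groups_order = ["control", "chir_short_early", "chir_short_late", "chir_long"]
    groups = [g for g in groups_order for _ in range(n_per_group)]
    n = len(groups)
    ebs = [f"EB{i:03d}" for i in range(n)]
    devA = rng.uniform(0.0, 20.0, size=n)
    w_latent = 2.0 - 0.15 * devA  # Wnt3 level set by developmental timing
    w_shift = np.array([_WNT3_SHIFT.get(g, 0.0) for g in groups])
    wnt3 = w_latent + w_shift + rng.normal(0.0, 0.3, size=n)
    sd_g = 1.0  # approximate control SD of each designed gene
    rows = {"Wnt3": wnt3}
    mode_truth: dict[str, str] = {}
    is_chir = np.array([g != "control" for g in groups])
    is_long = np.array([g == "chir_long" for g in groups])
    for mode in modes:
        for j in range(genes_per_mode):
            name = f"{mode}_{j}"
            b = rng.uniform(0.8, 1.4) * rng.choice([1.0, -1.0])
            eps = rng.normal(0.0, 0.4, size=n)
            if mode == "canonical_regulation":
                c = rng.uniform(3.5, 5.0) * sd_g * rng.choice([1.0, -1.0])
                g_val = b * w_latent + c * is_chir * np.where(is_long, 1.3, 1.0) + eps
            elif mode == "trend_continuation":
                g_val = b * wnt3 + rng.normal(0.0, 0.25, size=n)
            elif mode == "decoupled_parallel":
                g_val = b * w_latent + eps
            elif mode == "indirect_long_term_only":
                c = rng.uniform(3.5, 5.0) * sd_g * rng.choice([1.0, -1.0])
                g_val = b * w_latent + c * is_long + eps
            elif mode == "not_correlated":
                g_val = rng.normal(0.0, 1.0, size=n)
            else:  # pragma: no cover
                raise ValueError(f"unknown mode {mode!r}")
            rows[name] = g_val
            mode_truth[name] = mode
    neg = pd.DataFrame(rows, index=ebs).T
    metadata = pd.DataFrame({"group": groups, "devA_h": devA}, index=ebs)
    if as_ct:
        hk = [s for s in default_gene_panel() if s.housekeeping]
        panel = _emit_ct(neg, metadata, hk, rng)
        return panel, metadata, mode_truth
    return neg, metadata, mode_truth
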