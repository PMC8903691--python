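"""Synthetic MEG cohorts with planted directed source networks.

Real task-MEG recordings for this analysis are not publicly deposited, so the
pipeline ships a generator that produces sensor-level cohorts from fully known
ground truth:

* source dynamics are stable multivariate autoregressive (MVAR) processes,
  optionally band-shaped by filtering the innovations into a target frequency
  band.  MVAR sources make Granger-causal ground truth exact: a directed
  coupling coefficient from source j to source i IS the planted direction;
* sensors see a linear projection of the sources through a distance-kernel
  gain matrix plus white sensor noise at a requested SNR;
* two subject groups (patients / controls) differ in the prevalence of a
  planted prefrontal-to-temporal (PFC->TL) directed coupling, mirroring a
  case-control pattern contrast;
* each subject carries clinical covariates (headache history, attack
  frequency, duration, VAS, HAM-A, HAM-D).  Within the patient group one
  named covariate is tied to the subject's ground-truth network strength by a
  Gaussian-copula rank construction, so a target Spearman correlation can be
  planted without committing to any particular marginal distribution.

Each trial contains a trial-locked "evoked" source realization shared across
trials plus an independent "induced" realization per trial; both follow the
same MVAR coefficients, so trial averaging preserves the planted correlation
structure while concatenated single trials still carry the directed (lagged)
structure that Granger analysis needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .preprocessing import BandDefinition, get_band

__all__ = [
    "GAIN_SEED",
    "SourceNetworkSpec",
    "CohortSpec",
    "Recording",
    "companion_spectral_radius",
    "simulate_mvar",
    "make_gain_matrix",
    "draw_pattern_flags",
    "generate_cohort",
    "default_geometry",
    "default_network_specs",
    "CLINICAL_MARGINALS",
]

REGIONS = ("PFC", "TL", "OCC", "OTHER")

#: seed of the deterministic orientation jitter in the default forward model
GAIN_SEED = 1234


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class SourceNetworkSpec:
    """A stable MVAR source network.

    ``coupling`` has shape (model_order, n_sources, n_sources); entry
    ``coupling[k, i, j]`` is the influence of source j at lag k+1 on source i.
    ``noise_cov`` is the innovation covariance; off-diagonal innovation
    correlation plants instantaneous (zero-lag) correlation between sources,
    while ``coupling`` plants lagged, directed influence.
    """

    n_sources: int
    coupling: np.ndarray
    noise_cov: np.ndarray
    region_labels: tuple[str, ...]
    band: BandDefinition | None = None
    #: shape the source spectra by band-pass filtering the innovations; the
    #: default resonator networks instead shape the band through the AR
    #: dynamics and keep innovations white (exact finite-order VAR)
    filter_innovations: bool = False

    def __post_init__(self) -> None:
        coupling = np.asarray(self.coupling, dtype=float)
        if coupling.ndim != 3 or coupling.shape[1:] != (self.n_sources, self.n_sources):
            raise ValueError("coupling must have shape (order, n_sources, n_sources)")
        noise_cov = np.asarray(self.noise_cov, dtype=float)
        if noise_cov.shape != (self.n_sources, self.n_sources):
            raise ValueError("noise_cov must be n_sources x n_sources")
        if not np.allclose(noise_cov, noise_cov.T):
            raise ValueError("noise_cov must be symmetric")
        if np.linalg.eigvalsh(noise_cov).min() <= 0:
            raise ValueError("noise_cov must be positive definite")
        if len(self.region_labels) != self.n_sources:
            raise ValueError("region_labels length must equal n_sources")
        bad = set(self.region_labels) - set(REGIONS)
        if bad:
            raise ValueError(f"unknown region labels {sorted(bad)}")
        object.__setattr__(self, "coupling", coupling)
        object.__setattr__(self, "noise_cov", noise_cov)

    @property
    def model_order(self) -> int:
        return self.coupling.shape[0]

    @property
    def spectral_radius(self) -> float:
        return companion_spectral_radius(self.coupling)

    @property
    def is_stable(self) -> bool:
        return self.spectral_radius < 1.0


def companion_spectral_radius(coupling: np.ndarray) -> float:
    """Spectral radius of the MVAR companion matrix (< 1 means stationary)."""
    coupling = np.asarray(coupling, dtype=float)
    order, n, _ = coupling.shape
    companion = np.zeros((order * n, order * n))
    companion[:n] = coupling.transpose(1, 0, 2).reshape(n, order * n)
    if order > 1:
        companion[n:, :-n] = np.eye((order - 1) * n)
    return float(np.abs(np.linalg.eigvals(companion)).max())


@dataclass(frozen=True)
class CohortSpec:
    """Study-level design of a synthetic two-group cohort."""

    n_patients: int = 24
    n_controls: int = 24
    pattern_prevalence_patients: float = 19 / 24
    pattern_prevalence_controls: float = 8 / 24
    snr_db: float = 25.0
    n_trials: int = 60
    sfreq: float = 1000.0
    seed: int = 0
    clinical_rho: float = -0.5
    clinical_covariate: str = "ham_d"
    trial_len_s: float = 0.30
    trigger_s: float = 0.06
    n_channels: int = 64
    subject_scale_range: tuple[float, float] = (0.0, 1.0)
    induced_scale: float = 1.0

    def __post_init__(self) -> None:
        for p in (self.pattern_prevalence_patients, self.pattern_prevalence_controls):
            if not 0.0 <= p <= 1.0:
                raise ValueError("prevalences must be in [0, 1]")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.trigger_s >= self.trial_len_s:
            raise ValueError("trigger must fall inside the trial")

    @property
    def trial_samples(self) -> int:
        return int(round(self.trial_len_s * self.sfreq))

    @property
    def trigger_sample(self) -> int:
        return int(round(self.trigger_s * self.sfreq))


@dataclass
class Recording:
    """One subject's sensor-level recording plus metadata and ground truth."""

    data: np.ndarray  # channels x samples x trials
    sfreq: float
    trigger_sample: np.ndarray  # one trigger index per trial
    channel_positions: np.ndarray  # channels x 3, meters
    group: str  # "patient" | "control"
    clinical: dict[str, float | None]
    subject_id: str
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.trigger_sample = np.atleast_1d(np.asarray(self.trigger_sample, dtype=int))
        n_samples = self.data.shape[1]
        if np.any(self.trigger_sample < 0) or np.any(self.trigger_sample >= n_samples):
            raise ValueError("trigger_sample outside [0, samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]


# ---------------------------------------------------------------------------
# MVAR simulation

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    @njit(cache=False)
    def _var_recurse(coupling, innovations, out):  # pragma: no cover
        order, n, _ = coupling.shape
        total = out.shape[1]
        for t in range(order, total):
            for i in range(n):
                acc = innovations[i, t]
                for k in range(order):
                    for j in range(n):
                        acc += coupling[k, i, j] * out[j, t - 1 - k]
                out[i, t] = acc

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def _var_recurse(coupling, innovations, out):
        order = coupling.shape[0]
        total = out.shape[1]
        for t in range(order, total):
            acc = innovations[:, t].copy()
            for k in range(order):
                acc += coupling[k] @ out[:, t - 1 - k]
            out[:, t] = acc


def simulate_mvar(
    spec: SourceNetworkSpec,
    n_samples: int,
    seed: int | np.random.Generator,
    sfreq: float | None = None,
    burn_in: int = 500,
) -> np.ndarray:
    """Simulate one realization of the MVAR process; sources x samples.

    Innovations are Gaussian with covariance ``spec.noise_cov``; when
    ``spec.filter_innovations`` is set they are band-pass filtered into
    ``spec.band`` before entering the recursion (requires ``sfreq``).  The
    first ``burn_in`` samples are discarded so the output is (approximately)
    stationary.  Deterministic given the seed.
    """
    if not spec.is_stable:
        raise ValueError(
            f"unstable MVAR spec: companion spectral radius "
            f"{spec.spectral_radius:.3f} >= 1"
        )
    if n_samples <= 10 * spec.model_order:
        raise ValueError("n_samples must exceed 10 x model_order")
    if burn_in < 500:
        raise ValueError("burn_in must be >= 500")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    total = n_samples + burn_in
    chol = np.linalg.cholesky(spec.noise_cov)
    innovations = chol @ rng.standard_normal((spec.n_sources, total))
    if spec.band is not None and spec.filter_innovations:
        if sfreq is None:
            raise ValueError("sfreq is required for band-shaped innovations")
        from .preprocessing import bandpass

        innovations = np.ascontiguousarray(bandpass(innovations, sfreq, spec.band))
    out = np.zeros((spec.n_sources, total))
    out[:, : spec.model_order] = innovations[:, : spec.model_order]
    _var_recurse(spec.coupling, innovations, out)
    return out[:, burn_in:]


# ---------------------------------------------------------------------------
# forward model


def make_gain_matrix(
    n_channels: int,
    source_positions: np.ndarray,
    channel_positions: np.ndarray,
    seed: int | np.random.Generator = 0,
    jitter: float = 0.6,
) -> np.ndarray:
    """Dipole-like distance-kernel forward gain matrix (channels x sources).

    Entry magnitudes fall off with the inverse square of the channel-source
    distance; the sign and relative weighting come from the projection of a
    seeded random source orientation onto the channel direction (MEG lead
    fields are signed), plus a log-normal gain jitter.  Columns are
    normalized to unit norm.  This is deliberately not a physical head model
    — the pipeline only needs linear mixing with known ground truth — but the
    signed, orientation-diverse columns reproduce the property that matters
    for beamforming: distinct sources have weakly correlated topographies.
    """
    source_positions = np.atleast_2d(np.asarray(source_positions, dtype=float))
    channel_positions = np.atleast_2d(np.asarray(channel_positions, dtype=float))
    n_sources = source_positions.shape[0]
    if n_channels < n_sources:
        raise ValueError("need at least as many channels as sources")
    if channel_positions.shape[0] != n_channels:
        raise ValueError("channel_positions length must equal n_channels")
    diff = source_positions[None, :, :] - source_positions[:, None, :]
    dists = np.linalg.norm(diff, axis=-1)
    if np.any(dists[np.triu_indices(n_sources, k=1)] < 1e-9):
        raise ValueError("duplicate source positions give a rank-deficient gain")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    orient = rng.standard_normal((n_sources, 3))
    orient /= np.linalg.norm(orient, axis=1, keepdims=True)
    delta = channel_positions[:, None, :] - source_positions[None, :, :]
    d2 = np.sum(delta**2, axis=-1)
    unit = delta / np.sqrt(d2)[..., None]
    gain = np.sum(unit * orient[None, :, :], axis=-1) / (d2 + 1e-6)
    gain *= np.exp(jitter * rng.standard_normal(gain.shape))
    gain /= np.linalg.norm(gain, axis=0, keepdims=True)
    if np.linalg.matrix_rank(gain) < n_sources:
        raise ValueError("gain matrix is rank deficient; geometry is degenerate")
    return gain


def default_geometry(n_channels: int = 24) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Default 8-source head-like geometry and a sensor cap.

    Returns (source_positions, channel_positions, region_labels).  Two sources
    each in prefrontal (PFC), temporal (TL), occipital (OCC), and other
    cortex, all separated by well over the 10 mm voxel-merge radius; channels
    lie on a hemispherical cap of radius 9 cm.
    """
    source_positions = np.array(
        [
            [-0.020, 0.060, 0.040],  # PFC left
            [0.020, 0.060, 0.040],  # PFC right
            [-0.060, 0.000, 0.000],  # TL left
            [0.060, 0.000, 0.000],  # TL right
            [-0.020, -0.060, 0.020],  # OCC left
            [0.020, -0.060, 0.020],  # OCC right
            [-0.030, 0.000, 0.060],  # parietal
            [0.030, 0.000, 0.060],  # parietal
        ]
    )
    labels = ("PFC", "PFC", "TL", "TL", "OCC", "OCC", "OTHER", "OTHER")
    golden = np.pi * (3.0 - np.sqrt(5.0))
    idx = np.arange(n_channels)
    z = idx / max(n_channels - 1, 1)  # hemisphere: z in [0, 1]
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    theta = golden * idx
    channel_positions = 0.09 * np.column_stack(
        [r * np.cos(theta), r * np.sin(theta), z]
    )
    return source_positions, channel_positions, labels


# ---------------------------------------------------------------------------
# default study networks

#: posterior "background" cluster: PFC-1 plus occipital/parietal sources that
#: share a common innovation factor (excitatory frontal-occipital coupling,
#: the dominant pattern in healthy background networks).  The first two
#: members are always active; the rest switch on with the subject's latent
#: network-strength statistic.
_CLUSTER = (1, 5, 4, 6, 7)
_CLUSTER_CORR = 0.85
#: small directed baseline couplings (j -> i) inside the cluster
_BASELINE_COUPLINGS = (((1, 5), 0.12), ((6, 4), 0.12))
#: planted pattern: PFC (source 0) -> TL (source 2): a strong zero-lag
#: innovation correlation carries the correlation edge, a small lag-1
#: coefficient carries the Granger direction (narrow-band sources have short
#: memory, so a large lagged coefficient would decorrelate the pair instead)
_PLANTED_LAG_COEF = 0.15
_PLANTED_CORR = 0.97
#: AR(2) resonator pole radius; bandwidth of the source spectrum scales with
#: (1 - radius) * sfreq
_RESONATOR_R = 0.8


def _resonator_coupling(n: int, fc: float, sfreq: float, r: float = _RESONATOR_R) -> np.ndarray:
    """VAR(2) coefficients putting an AR(2) spectral resonance at fc on every
    source.  White innovations then give band-limited sources whose joint
    process is an exact finite-order VAR — which keeps Granger-causal ground
    truth exact and the GC F-test calibrated."""
    w = 2.0 * np.pi * fc / sfreq
    coupling = np.zeros((2, n, n))
    np.fill_diagonal(coupling[0], 2.0 * r * np.cos(w))
    np.fill_diagonal(coupling[1], -r * r)
    return coupling


def default_network_specs(
    band: BandDefinition | str = "gamma", sfreq: float = 1000.0
) -> tuple[SourceNetworkSpec, SourceNetworkSpec]:
    """The study-condition source networks: (pattern-present, pattern-absent).

    Every source is an AR(2) resonator centred on the band's centre frequency
    driven by white innovations.  Both networks share the posterior cluster
    (common innovation factor, pairwise correlation 0.85) plus weak directed
    occipital->frontal couplings; the pattern-present network adds the
    directed PFC->TL edge (innovation correlation 0.95 + lag-1 coefficient
    0.15).
    """
    if isinstance(band, str):
        band = get_band(band)
    n = 8
    coupling = _resonator_coupling(n, band.center, sfreq)
    noise_cov = np.eye(n)
    for i in _CLUSTER:
        for j in _CLUSTER:
            if i != j:
                noise_cov[i, j] = _CLUSTER_CORR
    for (i, j), c in _BASELINE_COUPLINGS:
        coupling[0, i, j] = c
    _, _, labels = default_geometry()
    absent = SourceNetworkSpec(n, coupling, noise_cov, labels, band=band)
    coupling_p = coupling.copy()
    noise_cov_p = noise_cov.copy()
    coupling_p[0, 2, 0] = _PLANTED_LAG_COEF
    noise_cov_p[2, 0] = noise_cov_p[0, 2] = _PLANTED_CORR
    present = SourceNetworkSpec(n, coupling_p, noise_cov_p, labels, band=band)
    return present, absent


def _subject_network(spec: SourceNetworkSpec, u: float) -> SourceNetworkSpec:
    """Subject-level network: the latent statistic u in [0, 1] sets how many
    optional cluster members are active.

    The first two cluster members are always on; each additional member (and
    any baseline coupling it feeds) switches on as u grows, so the subject's
    true background degree/strength is monotone in u.  The planted PFC->TL
    structure is untouched — pattern detectability does not depend on u.
    """
    always_on = 2
    n_extra = int(round(np.clip(u, 0.0, 1.0) * (len(_CLUSTER) - always_on)))
    inactive = set(_CLUSTER[always_on + n_extra :])
    if not inactive:
        return spec
    coupling = spec.coupling.copy()
    noise_cov = spec.noise_cov.copy()
    for m in inactive:
        for j in range(spec.n_sources):
            if j != m:
                noise_cov[m, j] = noise_cov[j, m] = 0.0
                coupling[:, m, j] = 0.0
                coupling[:, j, m] = 0.0
    return replace(spec, coupling=coupling, noise_cov=noise_cov)


# ---------------------------------------------------------------------------
# clinical covariates

#: marginal (mean, sd) of each clinical covariate per group; None = not
#: applicable (healthy controls have no headache phenotype)
CLINICAL_MARGINALS: dict[str, dict[str, tuple[float, float] | None]] = {
    "history_years": {"patient": (11.17, 6.62), "control": None},
    "freq_per_month": {"patient": (4.67, 4.40), "control": None},
    "duration_hours": {"patient": (20.76, 17.71), "control": None},
    "vas": {"patient": (7.42, 1.44), "control": None},
    "ham_a": {"patient": (9.67, 4.63), "control": (1.00, 0.65)},
    "ham_d": {"patient": (10.33, 5.11), "control": (1.58, 0.78)},
}


def _copula_correlated_normal(
    z_anchor: np.ndarray, rho_spearman: float, rng: np.random.Generator
) -> np.ndarray:
    """Normal scores with target Spearman correlation to ``z_anchor``.

    For a bivariate Gaussian copula the Spearman rho relates to the Pearson
    correlation r of the normal scores by rho = (6/pi) arcsin(r/2), inverted
    here as r = 2 sin(pi rho / 6).
    """
    r = 2.0 * np.sin(np.pi * rho_spearman / 6.0)
    eps = rng.standard_normal(z_anchor.shape)
    return r * z_anchor + np.sqrt(1.0 - r**2) * eps


def _draw_clinical(
    group: str,
    rng: np.random.Generator,
    anchor_z: float | None,
    rho: float,
    named: str,
) -> dict[str, float | None]:
    clinical: dict[str, float | None] = {}
    for cov, per_group in CLINICAL_MARGINALS.items():
        ms = per_group[group]
        if ms is None:
            clinical[cov] = None
            continue
        mean, sd = ms
        if cov == named and anchor_z is not None:
            z = _copula_correlated_normal(np.atleast_1d(anchor_z), rho, rng)[0]
        else:
            z = rng.standard_normal()
        clinical[cov] = float(max(0.0, mean + sd * z))
    return clinical


# ---------------------------------------------------------------------------
# cohort generation


def draw_pattern_flags(
    cohort: CohortSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Bernoulli pattern-presence flags for (patients, controls)."""
    flags_p = rng.random(cohort.n_patients) < cohort.pattern_prevalence_patients
    flags_c = rng.random(cohort.n_controls) < cohort.pattern_prevalence_controls
    return flags_p, flags_c


def _simulate_subject(
    net: SourceNetworkSpec,
    cohort: CohortSpec,
    gain: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sensor data (channels x samples x trials) for one subject.

    Source activity is stimulus-locked: sources are silent before the trigger
    (the pre-trigger interval is pure sensor noise, usable as a noise/baseline
    covariance window).  Each trial carries the subject's shared evoked
    realization plus an independent induced realization; both follow the same
    MVAR coefficients.
    """
    ts = cohort.trial_samples
    t0 = cohort.trigger_sample
    n_trials = cohort.n_trials
    # one long realization: first chunk = shared evoked, rest = per-trial induced
    long = simulate_mvar(net, (n_trials + 1) * ts, rng, sfreq=cohort.sfreq)
    evoked = long[:, :ts]
    induced = long[:, ts:].reshape(net.n_sources, n_trials, ts)
    sources = evoked[:, None, :] + cohort.induced_scale * induced
    sources[:, :, :t0] = 0.0  # stimulus-locked: silent pre-trigger baseline
    sensor = np.einsum("cs,stv->cvt", gain, sources)  # channels x ts x trials
    sig_var = sensor[:, t0:, :].var()
    noise_sd = np.sqrt(sig_var / 10.0 ** (cohort.snr_db / 10.0))
    sensor += noise_sd * rng.standard_normal(sensor.shape)
    return sensor


def generate_cohort(
    cohort: CohortSpec,
    net_patient: SourceNetworkSpec,
    net_control: SourceNetworkSpec,
) -> list[Recording]:
    """Generate a full two-group cohort of sensor-level recordings.

    ``net_patient`` is the pattern-present network, ``net_control`` the
    pattern-absent one; whether a given subject's network contains the planted
    pattern is a per-subject Bernoulli draw with the group's prevalence, so a
    minority of controls can carry the pattern just as a minority of patients
    can lack it.  Each subject additionally draws a latent network-strength
    statistic u (uniform over ``subject_scale_range``) that sets how many
    optional background-cluster sources are active; u is the ground-truth
    statistic to which the named clinical covariate is copula-linked
    (patients only, target Spearman ``clinical_rho``).  Fully deterministic
    given the cohort and network specifications.
    """
    band = net_patient.band
    if band is not None and band.hi * 2 >= cohort.sfreq:
        raise ValueError(
            f"sfreq {cohort.sfreq} violates Nyquist for band edge {band.hi} Hz"
        )
    src_pos, _, _ = default_geometry(cohort.n_channels)
    if net_patient.n_sources != src_pos.shape[0]:
        raise ValueError("default geometry supports 8-source networks")
    root = np.random.SeedSequence(cohort.seed)
    ss_design, *ss_subjects = root.spawn(1 + cohort.n_patients + cohort.n_controls)
    rng_design = np.random.default_rng(ss_design)
    _, chan_pos, labels = default_geometry(cohort.n_channels)
    # fixed gain seed: the forward model is part of the geometry, not of the
    # cohort randomness, so the analysis side can reconstruct it exactly
    gain = make_gain_matrix(cohort.n_channels, src_pos, chan_pos, seed=GAIN_SEED)
    flags_p, flags_c = draw_pattern_flags(cohort, rng_design)
    lo, hi = cohort.subject_scale_range
    recordings: list[Recording] = []
    idx = 0
    from scipy.stats import norm

    for group, flags in (("patient", flags_p), ("control", flags_c)):
        for k, present in enumerate(flags):
            rng = np.random.default_rng(ss_subjects[idx])
            scale = rng.uniform(lo, hi)
            base = net_patient if present else net_control
            net = _subject_network(base, scale)
            sensor = _simulate_subject(net, cohort, gain, rng)
            # anchor the copula on the normal score of the uniform scale draw
            u = (scale - lo) / (hi - lo) if hi > lo else 0.5
            anchor_z = norm.ppf(np.clip(u, 1e-12, 1 - 1e-12))
            clinical = _draw_clinical(
                group,
                rng,
                anchor_z if group == "patient" else None,
                cohort.clinical_rho,
                cohort.clinical_covariate,
            )
            recordings.append(
                Recording(
                    data=sensor,
                    sfreq=cohort.sfreq,
                    trigger_sample=np.full(cohort.n_trials, cohort.trigger_sample),
                    channel_positions=chan_pos,
                    group=group,
                    clinical=clinical,
                    subject_id=f"{group[:3]}{k:03d}",
                    ground_truth={
                        "pattern_present": bool(present),
                        "coupling_scale": float(scale),
                        "gt_statistic": float(scale),
                        "region_labels": list(labels),
                        "source_positions": src_pos.tolist(),
                        "band": None if band is None else band.name,
                    },
                )
            )
            idx += 1
    return recordings
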