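"""Deterministic forward model for a four-region speech repetition network.

The network has four regions in canonical order A1 (primary auditory
cortex), pSTS (posterior superior temporal sulcus), pOp (pars opercularis,
dorsal or ventral) and M1 (primary motor cortex, face or tongue/larynx
subregion).  All 16 ordered region pairs are connected except A1 -> M1,
giving 15 connections of which 4 are self-connections.  Auditory input
drives A1 only.

Neural dynamics are the standard deterministic DCM state equation

    dx/dt = A x + C u

with no bilinear (condition-modulation) term: the model estimates average
effective connectivity over a run.  Self-connections are parameterised as
-0.5 * exp(s_i) Hz so that a positive estimate means greater self-inhibition
and the system is stable at the prior mean.  The observation model is the
balloon-Windkessel haemodynamic model per region, reported as BOLD percent
signal change.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from ._core import neural_batch, hemo_batch, X_LIMIT

REGIONS = ("A1", "pSTS", "pOp", "M1")
N_REGIONS = 4

#: canonical label aliases used when naming subregional configurations
POP_VARIANTS = ("dpOp", "vpOp")
M1_VARIANTS = ("M1-f", "M1-tl")


class StructuralMismatchError(ValueError):
    """A parameter was supplied for a connection absent from the network."""


class InstabilityError(RuntimeError):
    """The neural trajectory diverged for the given parameters."""


class NumericalFailureError(RuntimeError):
    """The haemodynamic integration left its positive domain."""


# ---------------------------------------------------------------------------
# network architecture


@dataclass(frozen=True, eq=False)
class NetworkSpec:
    """Fixed four-region architecture.

    ``connection_mask[source, target]`` is True where a directed connection
    exists (including the diagonal = self-connections).  ``switchable_mask``
    marks the subset of extrinsic connections eligible for pruning during
    model-space search; self-connections are never switchable.
    """

    region_labels: tuple[str, str, str, str]
    connection_mask: np.ndarray
    input_region: int
    switchable_mask: np.ndarray

    def __post_init__(self):
        mask = np.asarray(self.connection_mask, bool)
        sw = np.asarray(self.switchable_mask, bool)
        if mask.shape != (N_REGIONS, N_REGIONS) or sw.shape != mask.shape:
            raise ValueError("masks must be 4x4")
        if len(self.region_labels) != N_REGIONS:
            raise ValueError("four region labels required")
        if sw[np.eye(N_REGIONS, dtype=bool)].any():
            raise ValueError("self-connections are not switchable")
        if (sw & ~mask).any():
            raise ValueError("switchable_mask must be a subset of connection_mask")
        object.__setattr__(self, "connection_mask", mask)
        object.__setattr__(self, "switchable_mask", sw)

    @property
    def n_connections(self) -> int:
        return int(self.connection_mask.sum())

    def extrinsic_pairs(self) -> tuple[tuple[int, int], ...]:
        """Ordered (source, target) pairs of extrinsic connections.

        Canonical order is (target, source) row-major, which fixes the
        layout of the flattened parameter vector.
        """
        pairs = []
        for tgt in range(N_REGIONS):
            for src in range(N_REGIONS):
                if src != tgt and self.connection_mask[src, tgt]:
                    pairs.append((src, tgt))
        return tuple(pairs)

    def switchable_pairs(self) -> tuple[tuple[int, int], ...]:
        return tuple((s, t) for (s, t) in self.extrinsic_pairs()
                     if self.switchable_mask[s, t])

    def pair_index(self, source: str | int, target: str | int) -> int:
        """Index of a named connection in the extrinsic parameter block."""
        s = self._region_index(source)
        t = self._region_index(target)
        try:
            return self.extrinsic_pairs().index((s, t))
        except ValueError:
            raise StructuralMismatchError(
                f"connection {self.region_labels[s]} -> "
                f"{self.region_labels[t]} is not part of the network")

    def _region_index(self, region: str | int) -> int:
        if isinstance(region, (int, np.integer)):
            return int(region)
        labels = list(self.region_labels)
        if region in labels:
            return labels.index(region)
        if region in REGIONS:  # generic role name (e.g. "pOp" for "dpOp")
            return REGIONS.index(region)
        raise KeyError(f"unknown region {region!r}")


def default_network(pop: str = "dpOp", m1: str = "M1-f") -> NetworkSpec:
    """The study architecture for one subregional configuration.

    All ordered pairs are connected except A1 -> M1 (15 connections, 4 of
    them self-connections); auditory input enters A1.  By default the
    switchable set is the 8 extrinsic connections excluding the three
    afferents to A1, giving a 2^8 = 256-model space.
    """
    if pop not in POP_VARIANTS or m1 not in M1_VARIANTS:
        raise ValueError(f"pop must be one of {POP_VARIANTS}, m1 one of {M1_VARIANTS}")
    mask = np.ones((N_REGIONS, N_REGIONS), dtype=bool)
    mask[0, 3] = False  # no A1 -> M1, by anatomical constraint
    switchable = mask & ~np.eye(N_REGIONS, dtype=bool)
    switchable[:, 0] = False  # afferents to A1 always retained
    return NetworkSpec(
        region_labels=("A1", "pSTS", pop, m1),
        connection_mask=mask,
        input_region=0,
        switchable_mask=switchable,
    )


def configuration_networks() -> dict[str, NetworkSpec]:
    """The four subregional configurations keyed by conventional name."""
    return {
        f"{m1}&{pop}": default_network(pop=pop, m1=m1)
        for m1 in M1_VARIANTS for pop in POP_VARIANTS
    }


# ---------------------------------------------------------------------------
# parameters


@dataclass
class ConnectivityParams:
    """Connectivity parameters of one subject-level model.

    ``extrinsic`` holds rate constants (Hz) aligned with
    ``NetworkSpec.extrinsic_pairs``; entries for masked-off pairs are
    structurally absent.  ``self_scaling`` are the dimensionless
    log-scalings of the fixed -0.5 Hz self-inhibition.  ``input_gain`` is
    the driving-input gain C into A1 (Hz per unit input).
    """

    extrinsic: np.ndarray
    self_scaling: np.ndarray
    input_gain: float

    def __post_init__(self):
        self.extrinsic = np.asarray(self.extrinsic, float)
        self.self_scaling = np.asarray(self.self_scaling, float)
        if self.self_scaling.shape != (N_REGIONS,):
            raise ValueError("self_scaling must have one entry per region")

    @classmethod
    def zeros(cls, spec: NetworkSpec) -> "ConnectivityParams":
        return cls(np.zeros(len(spec.extrinsic_pairs())), np.zeros(N_REGIONS), 0.0)

    @classmethod
    def from_dict(cls, spec: NetworkSpec,
                  extrinsic: dict[tuple[str, str], float] | None = None,
                  self_scaling: dict[str, float] | None = None,
                  input_gain: float = 0.0) -> "ConnectivityParams":
        """Build from named connections; unknown pairs raise."""
        out = cls.zeros(spec)
        out.input_gain = float(input_gain)
        for (src, tgt), value in (extrinsic or {}).items():
            out.extrinsic[spec.pair_index(src, tgt)] = value
        for region, value in (self_scaling or {}).items():
            out.self_scaling[spec._region_index(region)] = value
        return out


@dataclass
class HemodynamicParams:
    """Balloon-Windkessel parameters.

    Per-region log-scalings of the signal decay rate kappa0 and the venous
    transit time tau0 are estimated; the remaining constants are fixed at
    standard 3 T values.  k1..k3 are the BOLD coefficients for echo time TE
    with intra-/extravascular ratio epsilon.

    ``signal_scale`` fixes the output units at signal_scale x fractional
    signal change (500 = five times percent).  The unit is chosen so that
    block-design responses of this network land at amplitude ~3-5 and
    measurement noise at typical fMRI levels has variance near 1, which is
    the level the inversion's noise hyperprior expects (the same reason
    SPM rescales fMRI data to a maximum of ~4 before inverting a DCM).
    """

    decay_scaling: np.ndarray = field(default_factory=lambda: np.zeros(N_REGIONS))
    transit_scaling: np.ndarray = field(default_factory=lambda: np.zeros(N_REGIONS))
    signal_scale: float = 500.0
    kappa0: float = 0.64    # 1/s
    gamma: float = 0.32     # 1/s
    tau0: float = 2.0       # s
    alpha: float = 0.32     # Grubb exponent
    e0: float = 0.4         # resting oxygen extraction
    v0: float = 0.04        # resting venous volume fraction
    te: float = 0.030       # s
    nu0: float = 40.3       # 1/s
    r0: float = 25.0        # 1/s
    epsilon: float = 1.0

    def __post_init__(self):
        self.decay_scaling = np.asarray(self.decay_scaling, float)
        self.transit_scaling = np.asarray(self.transit_scaling, float)
        for name in ("kappa0", "tau0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.e0 < 1:
            raise ValueError("e0 must lie in (0, 1)")

    @property
    def kappa(self) -> np.ndarray:
        return self.kappa0 * np.exp(self.decay_scaling)

    @property
    def tau(self) -> np.ndarray:
        return self.tau0 * np.exp(self.transit_scaling)

    @property
    def k1(self) -> float:
        return 4.3 * self.nu0 * self.e0 * self.te

    @property
    def k2(self) -> float:
        return self.epsilon * self.r0 * self.e0 * self.te

    @property
    def k3(self) -> float:
        return 1.0 - self.epsilon


@dataclass
class DCMParameters:
    """Full parameter vector of one subject-level model."""

    conn: ConnectivityParams
    hemo: HemodynamicParams = field(default_factory=HemodynamicParams)

    def flatten(self, spec: NetworkSpec) -> np.ndarray:
        """Canonical flattening: extrinsic rates (by (target, source)
        row-major over masked pairs), 4 self-scalings, input gain, then
        4 decay and 4 transit scalings."""
        n_ext = len(spec.extrinsic_pairs())
        if self.conn.extrinsic.shape != (n_ext,):
            raise StructuralMismatchError(
                f"expected {n_ext} extrinsic rates, got {self.conn.extrinsic.shape}")
        return np.concatenate([
            self.conn.extrinsic,
            self.conn.self_scaling,
            [self.conn.input_gain],
            self.hemo.decay_scaling,
            self.hemo.transit_scaling,
        ])

    @classmethod
    def from_vector(cls, theta: np.ndarray, spec: NetworkSpec,
                    hemo_template: HemodynamicParams | None = None) -> "DCMParameters":
        theta = np.asarray(theta, float)
        n_ext = len(spec.extrinsic_pairs())
        if theta.shape != (n_ext + 2 * N_REGIONS + 1 + N_REGIONS,):
            raise StructuralMismatchError(
                f"parameter vector has wrong length {theta.shape}")
        conn = ConnectivityParams(
            extrinsic=theta[:n_ext].copy(),
            self_scaling=theta[n_ext:n_ext + N_REGIONS].copy(),
            input_gain=float(theta[n_ext + N_REGIONS]),
        )
        base = hemo_template or HemodynamicParams()
        hemo = dataclasses.replace(
            base,
            decay_scaling=theta[n_ext + N_REGIONS + 1:n_ext + 2 * N_REGIONS + 1].copy(),
            transit_scaling=theta[n_ext + 2 * N_REGIONS + 1:].copy(),
        )
        return cls(conn=conn, hemo=hemo)


def n_parameters(spec: NetworkSpec) -> int:
    return len(spec.extrinsic_pairs()) + 3 * N_REGIONS + 1


# ---------------------------------------------------------------------------
# stimulus design


@dataclass
class StimulusDesign:
    """Block (and optionally event) timing of one scanning run."""

    block_onsets: np.ndarray
    block_durations: np.ndarray
    tr: float
    n_volumes: int
    microtime_bins_per_tr: int = 16
    event_onsets: np.ndarray | None = None
    event_durations: np.ndarray | None = None

    def __post_init__(self):
        self.block_onsets = np.asarray(self.block_onsets, float)
        self.block_durations = np.asarray(self.block_durations, float)
        if self.block_onsets.shape != self.block_durations.shape:
            raise ValueError("onsets and durations must align")
        if (self.block_durations <= 0).any():
            raise ValueError("all durations must be positive")
        if self.microtime_bins_per_tr < 1:
            raise ValueError("microtime_bins_per_tr must be >= 1")
        run_length = self.n_volumes * self.tr
        if self.block_onsets.size and \
                np.max(self.block_onsets + self.block_durations) > run_length + 1e-9:
            raise ValueError("blocks extend beyond the run")
        order = np.argsort(self.block_onsets)
        ends = (self.block_onsets + self.block_durations)[order]
        starts = self.block_onsets[order]
        if (starts[1:] < ends[:-1] - 1e-9).any():
            raise ValueError("overlapping blocks")

    @property
    def dt(self) -> float:
        """Microtime step (s)."""
        return self.tr / self.microtime_bins_per_tr

    @property
    def n_bins(self) -> int:
        return self.n_volumes * self.microtime_bins_per_tr


def build_input(design: StimulusDesign, events: bool = False) -> np.ndarray:
    """Unit-height box-car input on the microtime grid.

    ``u[k]`` applies over the bin [k*dt, (k+1)*dt); a bin is on when its
    start time falls inside a stimulation block (or event, with
    ``events=True``).
    """
    if events:
        if design.event_onsets is None:
            raise ValueError("design has no event timing")
        onsets = np.asarray(design.event_onsets, float)
        durations = np.asarray(design.event_durations, float)
    else:
        onsets, durations = design.block_onsets, design.block_durations
    t = np.arange(design.n_bins) * design.dt
    u = np.zeros(design.n_bins)
    for onset, dur in zip(onsets, durations):
        u[(t >= onset - 1e-9) & (t < onset + dur - 1e-9)] = 1.0
    return u


# ---------------------------------------------------------------------------
# time series container


@dataclass
class RegionTimeSeries:
    """BOLD time series for the four regions (columns) over volumes (rows)."""

    values: np.ndarray
    tr: float
    region_labels: tuple[str, ...] = REGIONS

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2 or self.values.shape[1] != N_REGIONS:
            raise ValueError("values must be (n_volumes, 4)")
        if not np.isfinite(self.values).all():
            raise ValueError("missing or non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    def centred(self) -> "RegionTimeSeries":
        return RegionTimeSeries(self.values - self.values.mean(axis=0),
                                self.tr, self.region_labels)


# ---------------------------------------------------------------------------
# forward model operations


def build_effective_A(conn: ConnectivityParams, spec: NetworkSpec) -> np.ndarray:
    """Effective connectivity matrix A with A[target, source] (Hz).

    Diagonal entries are -0.5*exp(self_scaling); off-diagonal entries are
    the extrinsic rates where the mask allows, exactly zero elsewhere
    (A1 -> M1 in particular).
    """
    pairs = spec.extrinsic_pairs()
    if conn.extrinsic.shape != (len(pairs),):
        raise StructuralMismatchError(
            f"expected {len(pairs)} extrinsic rates, got {conn.extrinsic.shape[0]}")
    A = np.zeros((N_REGIONS, N_REGIONS))
    A[np.arange(N_REGIONS), np.arange(N_REGIONS)] = -0.5 * np.exp(conn.self_scaling)
    for k, (src, tgt) in enumerate(pairs):
        A[tgt, src] = conn.extrinsic[k]
    return A


def _discretise(A: np.ndarray, cvec: np.ndarray, dt: float):
    """Exact one-bin propagator: x+ = E x + M u with u constant on the bin.

    Uses the augmented-matrix exponential so that singular A is handled.
    """
    n = A.shape[0]
    aug = np.zeros((n + 1, n + 1))
    aug[:n, :n] = A
    aug[:n, n] = cvec
    P = expm(aug * dt)
    return P[:n, :n], P[:n, n]


def integrate_neural(A: np.ndarray, c: float, u: np.ndarray, dt: float,
                     input_region: int = 0) -> np.ndarray:
    """Neural states at bin edges (T+1, 4), exact per bin; x(0) = 0."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    cvec = np.zeros(A.shape[0])
    cvec[input_region] = c
    E, M = _discretise(A, cvec, dt)
    x, ok = neural_batch(E[None], M[None], np.asarray(u, float))
    if not ok[0]:
        raise InstabilityError(
            f"neural trajectory exceeded |x| = {X_LIMIT:g}; "
            f"A diagonal = {np.diag(A)}, input gain = {c}")
    return x[0]


def hemodynamics(x: np.ndarray, h: HemodynamicParams, dt: float) -> np.ndarray:
    """BOLD percent signal on the microtime grid, same shape as ``x``.

    ``x[t]`` drives the balloon ODEs over bin t; the returned ``y[t]`` is
    evaluated from the state at time t*dt, so rest reproduces y = 0.
    """
    x = np.asarray(x, float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    n_reg = x.shape[1]
    kappa = np.broadcast_to(np.resize(h.kappa, n_reg), (1, n_reg)).copy()
    tau = np.broadcast_to(np.resize(h.tau, n_reg), (1, n_reg)).copy()
    y, ok = hemo_batch(x[None], kappa, tau, h.gamma, h.alpha, h.e0,
                       h.signal_scale * h.v0, h.k1, h.k2, h.k3, dt)
    if not ok[0]:
        raise NumericalFailureError(
            "haemodynamic state left its positive domain; "
            "use a smaller microtime step")
    return y[0, :, 0] if squeeze else y[0]


def predict_bold(theta: DCMParameters, design: StimulusDesign,
                 spec: NetworkSpec, u: np.ndarray | None = None) -> RegionTimeSeries:
    """Predicted BOLD series: input -> neural -> haemodynamics -> sampling.

    The microtime output is decimated at end-of-volume times t = TR, 2 TR,
    ... and mean-centred per region.
    """
    vec = theta.flatten(spec)
    Y, ok = _forward_batch(vec[None], design, spec, u=u,
                           hemo_template=theta.hemo)
    if not ok[0]:
        raise InstabilityError(
            f"forward model diverged for parameters {vec}")
    return RegionTimeSeries(Y[0], design.tr, spec.region_labels)


def _forward_batch(thetas: np.ndarray, design: StimulusDesign,
                   spec: NetworkSpec, u: np.ndarray | None = None,
                   hemo_template: HemodynamicParams | None = None):
    """Batched forward model over parameter vectors.

    Returns (Y, ok): Y is (B, n_volumes, 4) mean-centred BOLD percent;
    ok flags rows whose integration failed (diverged or left the balloon
    domain) -- their Y rows are zero.
    """
    thetas = np.atleast_2d(np.asarray(thetas, float))
    B = thetas.shape[0]
    if u is None:
        u = build_input(design)
    h0 = hemo_template or HemodynamicParams()
    n_ext = len(spec.extrinsic_pairs())
    dt = design.dt

    E = np.empty((B, N_REGIONS, N_REGIONS))
    M = np.empty((B, N_REGIONS))
    kappa = np.empty((B, N_REGIONS))
    tau = np.empty((B, N_REGIONS))
    for b in range(B):
        th = DCMParameters.from_vector(thetas[b], spec, hemo_template=h0)
        A = build_effective_A(th.conn, spec)
        cvec = np.zeros(N_REGIONS)
        cvec[spec.input_region] = th.conn.input_gain
        E[b], M[b] = _discretise(A, cvec, dt)
        kappa[b] = th.hemo.kappa
        tau[b] = th.hemo.tau

    x, ok_n = neural_batch(E, M, u)
    y, ok_h = hemo_batch(x, kappa, tau, h0.gamma, h0.alpha, h0.e0,
                         h0.signal_scale * h0.v0, h0.k1, h0.k2, h0.k3, dt)
    ok = ok_n & ok_h
    idx = np.arange(1, design.n_volumes + 1) * design.microtime_bins_per_tr
    Y = y[:, idx, :]
    Y = Y - Y.mean(axis=1, keepdims=True)
    Y[~ok] = 0.0
    return Y, ok
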