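"""Pulsatile rigid-tube flow: Womersley wall shear from a flow waveform.

Stands in for a full 3-D flow solve when generating synthetic wall-shear
fields: given a periodic volumetric flow waveform Q(t) through a straight
rigid tube of radius R, the axisymmetric unsteady Stokes solution gives the
axial wall shear stress per harmonic.  The steady component is the
Poiseuille value tau_0 = 4*mu*Q0/(pi*R^3); each harmonic n is solved with
the pressure-gradient amplitude scaled so the harmonic's flow matches the
waveform, and the wall shear is mu times the radial velocity gradient at
the wall.

Units at the interface: radius mm, flow ml/min, shear Pa, time s;
SI internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import jv

#: default blood dynamic viscosity (Pa s) and density (kg m^-3)
BLOOD_VISCOSITY = 3.5e-3
BLOOD_DENSITY = 1050.0

ML_MIN_TO_M3_S = 1e-6 / 60.0
MM_TO_M = 1e-3


@dataclass
class FlowWaveform:
    """Periodic volumetric flow waveform as steady value + complex harmonics.

    Q(t) [ml/min] = mean_flow + sum_n Re( A_n * exp(i*n*Omega*t) ),
    Omega = 2*pi/period.

    Parameters
    ----------
    period : cardiac period T (s), > 0.
    mean_flow : cycle-averaged flow Q0 (ml/min).
    harmonics : list of (harmonic index n >= 1, complex amplitude A_n in
        ml/min).
    sample_times : strictly increasing times covering one period,
        first = 0, last < period.
    """

    period: float
    mean_flow: float
    harmonics: list[tuple[int, complex]] = field(default_factory=list)
    sample_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")
        for n, _ in self.harmonics:
            if int(n) < 1:
                raise ValueError("harmonic indices must be >= 1")
        if self.sample_times is None:
            self.sample_times = np.linspace(0.0, self.period, 64, endpoint=False)
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        t = self.sample_times
        if t[0] != 0.0 or t[-1] >= self.period or np.any(np.diff(t) <= 0):
            raise ValueError(
                "sample_times must be strictly increasing, start at 0 and end before the period"
            )

    @property
    def omega(self) -> float:
        """Fundamental angular frequency Omega = 2*pi/T (rad/s)."""
        return 2.0 * np.pi / self.period

    def reconstruct(self, t: np.ndarray | float | None = None) -> np.ndarray:
        """Q(t) in ml/min at the given times (default: sample_times)."""
        if t is None:
            t = self.sample_times
        t = np.asarray(t, dtype=float)
        q = np.full(t.shape, float(self.mean_flow))
        for n, a in self.harmonics:
            q = q + np.real(a * np.exp(1j * n * self.omega * t))
        return q

    @classmethod
    def physiologic(
        cls,
        mean_flow: float = 600.0,
        period: float = 1.0,
        pulsatility: float = 0.5,
        n_samples: int = 64,
    ) -> "FlowWaveform":
        """Default preset: steady component plus two harmonics.

        ``pulsatility`` scales the first-harmonic amplitude relative to the
        mean; the second harmonic is 40% of the first with a phase lag,
        giving the skewed systolic peak typical of arterial waveforms while
        keeping Q(t) > 0.
        """
        a1 = pulsatility * mean_flow * np.exp(-1j * np.pi / 2)
        a2 = 0.4 * pulsatility * mean_flow * np.exp(-1j * np.pi)
        wf = cls(
            period=period,
            mean_flow=mean_flow,
            harmonics=[(1, a1), (2, a2)],
            sample_times=np.linspace(0.0, period, n_samples, endpoint=False),
        )
        if np.any(wf.reconstruct() <= 0):
            raise ValueError("physiologic preset requires Q(t) > 0; reduce pulsatility")
        return wf


@dataclass
class WallShearSeries:
    """Signed axial wall shear tau(t) (Pa) over one period.

    ``signed`` is the axial traction exerted by the fluid on the wall,
    positive in the mean-flow direction; ``steady`` is the Poiseuille
    component 4*mu*Q0/(pi*R^3).
    """

    times: np.ndarray
    signed: np.ndarray
    steady: float
    period: float

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.signed)


def poiseuille_wall_shear(radius_mm: float, flow_ml_min: float, viscosity: float = BLOOD_VISCOSITY) -> float:
    """Steady wall shear 4*mu*Q/(pi*R^3) in Pa."""
    r = radius_mm * MM_TO_M
    q = flow_ml_min * ML_MIN_TO_M3_S
    return 4.0 * viscosity * q / (np.pi * r**3)


def womersley_number(radius_mm: float, angular_freq: float,
                     density: float = BLOOD_DENSITY, viscosity: float = BLOOD_VISCOSITY) -> float:
    """alpha = R * sqrt(omega * rho / mu)."""
    return radius_mm * MM_TO_M * np.sqrt(angular_freq * density / viscosity)


def _harmonic_shear_factor_bessel(alpha: float) -> complex:
    """Complex ratio tau_n / (mu * Q_n / (pi R^3)) for Womersley number alpha.

    With Lambda = i^{3/2} alpha, the rigid-tube harmonic solution gives
    tau_n = -mu*Q_n/(pi R^3) * Lambda*J1(Lambda) / ( J0(Lambda) *
    (1 - 2 J1(Lambda)/(Lambda J0(Lambda))) ); as alpha -> 0 this tends to
    the quasi-steady factor 4.
    """
    lam = 1j**1.5 * alpha
    j0, j1 = jv(0, lam), jv(1, lam)
    denom = j0 * (1.0 - 2.0 * j1 / (lam * j0))
    return -lam * j1 / denom


def _harmonic_shear_factor_fd(alpha: float, n_nodes: int = 400) -> complex:
    """Finite-difference evaluation of the same factor (fallback path).

    Solves the complex harmonic momentum equation
    i*alpha^2*u = g + u'' + u'/r on r in [0, 1] with u(1) = 0, u'(0) = 0,
    for unit forcing g, then forms tau/(mu*Q/(pi R^3)) = -u'(1)*pi /
    (2*pi*int r u dr) * ... directly in nondimensional variables.
    """
    r = np.linspace(0.0, 1.0, n_nodes)
    h = r[1] - r[0]
    n = n_nodes
    A = np.zeros((n, n), dtype=complex)
    b = np.zeros(n, dtype=complex)
    # interior: u'' + u'/r - i alpha^2 u = -g  (g = 1)
    for i in range(1, n - 1):
        A[i, i - 1] = 1.0 / h**2 - 1.0 / (2 * h * r[i])
        A[i, i] = -2.0 / h**2 - 1j * alpha**2
        A[i, i + 1] = 1.0 / h**2 + 1.0 / (2 * h * r[i])
        b[i] = -1.0
    # r = 0: symmetry, u'' term becomes 4(u1 - u0)/h^2 (L'Hopital: u'/r -> u'')
    A[0, 0] = -4.0 / h**2 - 1j * alpha**2
    A[0, 1] = 4.0 / h**2
    b[0] = -1.0
    A[-1, -1] = 1.0  # no-slip
    u = np.linalg.solve(A, b)
    # flow per unit forcing: Q* = 2*pi*int_0^1 u r dr ; wall gradient u'(1)
    qstar = 2.0 * np.pi * np.trapezoid(u * r, r)
    du_wall = (3 * u[-1] - 4 * u[-2] + u[-3]) / (2 * h)
    # tau = -mu du/dr|wall ; normalised by mu*Q/(pi R^3): factor = -u'(1)*pi/Q*
    return -du_wall * np.pi / qstar


def womersley_wall_shear(
    radius: float,
    waveform: FlowWaveform,
    viscosity: float = BLOOD_VISCOSITY,
    density: float = BLOOD_DENSITY,
    times: np.ndarray | None = None,
) -> WallShearSeries:
    """Signed axial wall shear of pulsatile flow in a rigid tube.

    Parameters
    ----------
    radius : tube radius (mm).
    waveform : periodic flow waveform (ml/min).
    viscosity, density : blood properties (Pa s, kg m^-3).
    times : evaluation times over one period (default: waveform samples).

    Returns
    -------
    WallShearSeries with tau(t) in Pa.  The time mean of the signed shear
    equals the steady Poiseuille value by linearity of the solution.
    """
    if radius <= 0 or viscosity <= 0 or density <= 0:
        raise ValueError("radius, viscosity and density must be positive")
    if times is None:
        times = waveform.sample_times
    times = np.asarray(times, dtype=float)
    tau0 = poiseuille_wall_shear(radius, waveform.mean_flow, viscosity)
    tau = np.full(times.shape, tau0, dtype=float)
    r_m = radius * MM_TO_M
    base = viscosity / (np.pi * r_m**3)
    for n, a in waveform.harmonics:
        alpha = womersley_number(radius, n * waveform.omega, density, viscosity)
        factor = _harmonic_shear_factor_bessel(alpha)
        if not np.isfinite(factor):
            warnings.warn(
                f"Bessel evaluation unstable at alpha={alpha:.1f}; "
                "falling back to the finite-difference harmonic solve",
                RuntimeWarning,
            )
            factor = _harmonic_shear_factor_fd(alpha)
        q_n = a * ML_MIN_TO_M3_S  # complex flow amplitude, m^3/s
        tau_n = base * factor * q_n
        tau = tau + np.real(tau_n * np.exp(1j * n * waveform.omega * times))
    return WallShearSeries(times=times, signed=tau, steady=tau0, period=waveform.period)


def harmonic_pressure_gradients(
    radius: float,
    waveform: FlowWaveform,
    viscosity: float = BLOOD_VISCOSITY,
    density: float = BLOOD_DENSITY,
) -> list[tuple[int, complex]]:
    """Complex pressure-gradient amplitudes G_n (Pa/m) matching the waveform.

    -dp/dx(t) = G_0 + sum_n Re(G_n exp(i n Omega t)); G_0 is the Poiseuille
    gradient 8*mu*Q0/(pi*R^4).  Used to drive independent time-stepping
    checks of the analytic solution.
    """
    r_m = radius * MM_TO_M
    q0 = waveform.mean_flow * ML_MIN_TO_M3_S
    out = [(0, 8.0 * viscosity * q0 / (np.pi * r_m**4))]
    for n, a in waveform.harmonics:
        w = n * waveform.omega
        lam = 1j**1.5 * womersley_number(radius, w, density, viscosity)
        q_n = a * ML_MIN_TO_M3_S
        # Q_n = G_n * pi R^2/(i rho w) * (1 - 2 J1/(lam J0))
        bracket = 1.0 - 2.0 * jv(1, lam) / (lam * jv(0, lam))
        g_n = q_n * (1j * density * w) / (np.pi * r_m**2 * bracket)
        out.append((n, g_n))
    return out
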