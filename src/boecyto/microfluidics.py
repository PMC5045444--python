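"""Hydraulics of the 3D hydrodynamic-focusing chip.

The chip confines the sample stream vertically with four sheath branches and
then horizontally with two, all fed from a single sheath inlet.  Because the
off-chip tubing resistance is negligible, the vertical and horizontal sheath
paths see the same pressure drop, so the sheath split Q_HS/Q_VS is fixed by
the laminar flow resistances alone:

    ΔP = Σ_i 32 υ ρ K_P,i (l_i / d_i²) (Q_i / A_i),   d_i = 2 a_i b_i/(a_i+b_i),

with K_P an empirical correction for the high-aspect horizontal segment and
an additive offset K_Q absorbing junction effects (both taken as given
constants, 1.4 and 0.75).  The focused core travels at the centerline of the
straight rectangular channel, where the laminar profile is the classical
Fourier series

    v(y, z) = (4b²/μπ³)(−dP/dx) Σ_n (−1)ⁿ/(2n+1)³
              {1 − cosh[(2n+1)πy/b]/cosh[(2n+1)πa/2b]} cos[(2n+1)πz/b],

y ∈ [−a/2, a/2] across the width, z ∈ [−b/2, b/2] across the height; the
centerline-to-mean ratio v(0,0)/V_AVR runs from 2.0962 (square duct) down to
1.5 (parallel-plate limit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

WATER_KINEMATIC_VISCOSITY = 1.004e-6  # m²/s at 20 °C
WATER_DENSITY = 998.0  # kg/m³


class DomainError(ValueError):
    """A requested point lies outside the duct cross-section."""


@dataclass(frozen=True)
class ChannelSegment:
    """One rectangular channel segment of the resistance network.

    ``parallel_count`` identical branches share the path flow equally (4 for
    the vertical-sheath feed, 2 for the horizontal); ``carries_sample`` marks
    segments downstream of the sample junction, which additionally carry the
    sample rate Q_S; ``k_p`` is the high-aspect-ratio resistance correction.
    """

    width: float
    height: float
    length: float
    parallel_count: int = 1
    k_p: float = 1.0
    carries_sample: bool = False

    def __post_init__(self) -> None:
        if min(self.width, self.height, self.length) <= 0:
            raise ValueError("segment dimensions must be strictly positive")
        if self.parallel_count < 1:
            raise ValueError("parallel_count must be >= 1")

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def hydraulic_diameter(self) -> float:
        return hydraulic_diameter(self.width, self.height)

    @property
    def resistance_geometry(self) -> float:
        """The purely geometric factor K_P · l / (parallel · A · d²) (m⁻⁴)."""
        return self.k_p * self.length / (
            self.parallel_count * self.area * self.hydraulic_diameter**2
        )


@dataclass(frozen=True)
class FlowConfig:
    """Fluid properties and operating rates (SI units).

    Defaults: distilled water at 20 °C, the reference operating point
    (60 μl/min sample, 7.2 ml/min sheath), and the chip's calibration
    constants K_Q = 0.75.
    """

    kinematic_viscosity: float = WATER_KINEMATIC_VISCOSITY
    density: float = WATER_DENSITY
    sample_rate: float = 60e-9 / 60  # 60 μl/min in m³/s
    sheath_rate: float = 7.2e-6 / 60  # 7.2 ml/min in m³/s
    k_q: float = 0.75

    def __post_init__(self) -> None:
        if min(self.kinematic_viscosity, self.density) <= 0:
            raise ValueError("fluid properties must be strictly positive")
        if min(self.sample_rate, self.sheath_rate) < 0:
            raise ValueError("flow rates must be non-negative")

    @property
    def dynamic_viscosity(self) -> float:
        """μ = υ·ρ (Pa·s)."""
        return self.kinematic_viscosity * self.density


@dataclass(frozen=True)
class ChannelNetwork:
    """Vertical (feed 1–4 + shared 5–6) and horizontal (7–8) sheath paths."""

    vertical_path: tuple[ChannelSegment, ...]
    horizontal_path: tuple[ChannelSegment, ...]

    def __post_init__(self) -> None:
        if not self.vertical_path or not self.horizontal_path:
            raise ValueError("both paths need at least one segment")


def example_network() -> ChannelNetwork:
    """An illustrative focusing-chip network with sheath split near 8.

    The reference chip's per-segment lengths are design-file quantities; this
    instance uses plausible 150 μm-layer channel dimensions chosen so the
    resistance-set split ratio lands near the design optimum Q_HS/Q_VS ≈ 8.
    """
    feed = ChannelSegment(width=300e-6, height=150e-6, length=17.6e-3, parallel_count=4)
    shared5 = ChannelSegment(
        width=300e-6, height=150e-6, length=1.5e-3, carries_sample=True
    )
    shared6 = ChannelSegment(
        width=310e-6, height=163e-6, length=1.5e-3, carries_sample=True
    )
    horiz = ChannelSegment(
        width=600e-6, height=150e-6, length=4.0e-3, parallel_count=2, k_p=1.4
    )
    return ChannelNetwork(
        vertical_path=(feed, shared5, shared6), horizontal_path=(horiz,)
    )


def hydraulic_diameter(a: float, b: float) -> float:
    """d = 2ab/(a+b) for an a × b rectangular duct (m)."""
    if a <= 0 or b <= 0:
        raise ValueError("duct sides must be strictly positive")
    return 2 * a * b / (a + b)


def path_pressure_drop(
    path,
    q_path: float,
    fluid: FlowConfig,
    include_sample_flow: bool = True,
) -> float:
    """Laminar pressure drop (Pa) along a series of segments carrying q_path.

    Each segment contributes 32·υ·ρ·K_P·(l/d²)·(Q_seg/A) with
    Q_seg = q_path / parallel_count; segments flagged ``carries_sample``
    additionally carry the sample rate unless ``include_sample_flow`` is
    False (the drop-Q_S approximation).
    """
    if q_path < 0:
        raise ValueError("path flow rate must be non-negative")
    coef = 32 * fluid.kinematic_viscosity * fluid.density
    drop = 0.0
    for seg in path:
        q_seg = q_path / seg.parallel_count
        if seg.carries_sample and include_sample_flow:
            q_seg += fluid.sample_rate
        drop += coef * seg.k_p * seg.length / seg.hydraulic_diameter**2 * (
            q_seg / seg.area
        )
    return drop


def flow_split_ratio(network: ChannelNetwork, fluid: FlowConfig) -> float:
    """Sheath split Q_HS/Q_VS from the resistance balance.

    Ratio of the vertical-path geometric resistance sum to the K_P-corrected
    horizontal one, plus the junction offset K_Q.
    """
    r_vertical = sum(s.resistance_geometry for s in network.vertical_path)
    r_horizontal = sum(s.resistance_geometry for s in network.horizontal_path)
    if r_horizontal <= 0:
        raise ZeroDivisionError("horizontal path has zero resistance")
    return r_vertical / r_horizontal + fluid.k_q


def split_rates(network: ChannelNetwork, fluid: FlowConfig) -> tuple[float, float]:
    """(Q_HS, Q_VS) partition of the sheath rate implied by the network."""
    ratio = flow_split_ratio(network, fluid)
    q_vs = fluid.sheath_rate / (1 + ratio)
    return fluid.sheath_rate - q_vs, q_vs


# ---------------------------------------------------------------------------
# rectangular-duct laminar profile


@dataclass(frozen=True)
class DuctProfile:
    """Fully developed laminar flow in an a × b rectangular duct.

    Driven either by an explicit pressure gradient or by a total rate Q (the
    gradient is then recovered from the analytic series flow rate).  The
    series truncation error falls off as the 1/(2n+1)³ tail; 100 terms keep
    it far below every tolerance used here.
    """

    width: float
    height: float
    dynamic_viscosity: float = WATER_KINEMATIC_VISCOSITY * WATER_DENSITY
    pressure_gradient: float | None = None  # −dP/dx, Pa/m
    total_rate: float | None = None  # m³/s
    series_terms: int = 100

    def __post_init__(self) -> None:
        if min(self.width, self.height) <= 0 or self.dynamic_viscosity <= 0:
            raise ValueError("duct geometry and viscosity must be positive")
        if self.series_terms < 25:
            raise ValueError("series_terms must be >= 25 for convergence")
        if (self.pressure_gradient is None) == (self.total_rate is None):
            raise ValueError("give exactly one of pressure_gradient / total_rate")

    def _gradient(self) -> float:
        if self.pressure_gradient is not None:
            return self.pressure_gradient
        unit = _series_flow_rate(self.width, self.height, self.dynamic_viscosity, 1.0,
                                 self.series_terms)
        return self.total_rate / unit

    def flow_rate(self) -> float:
        """Analytic series integral of v over the cross-section (m³/s)."""
        if self.total_rate is not None:
            return self.total_rate
        return _series_flow_rate(
            self.width, self.height, self.dynamic_viscosity,
            self.pressure_gradient, self.series_terms,
        )

    def mean_velocity(self) -> float:
        return self.flow_rate() / (self.width * self.height)


def _series_terms_arrays(terms: int):
    n = np.arange(terms)
    return n, (2 * n + 1)


def _series_flow_rate(a, b, mu, gradient, terms) -> float:
    _, odd = _series_terms_arrays(terms)
    beta = odd * np.pi / b
    per_term = (2 / beta) ** 2 / odd**3 * (
        a * beta / 2 - np.tanh(beta * a / 2)
    )
    # ∫∫ v dy dz, the (−1)ⁿ factors of the two axis integrals cancel
    return float(4 * b**2 / (mu * np.pi**3) * gradient * np.sum(per_term))


def duct_velocity(profile: DuctProfile, y, z):
    """Series velocity v(y, z) (m/s); y across the width, z across the height.

    Coordinates are centered on the duct axis; points outside the
    cross-section raise :class:`DomainError`.
    """
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    a, b = profile.width, profile.height
    if np.any(np.abs(y) > a / 2 + 1e-15) or np.any(np.abs(z) > b / 2 + 1e-15):
        raise DomainError("point outside the duct cross-section")
    n, odd = _series_terms_arrays(profile.series_terms)
    sign = (-1.0) ** n
    arg = odd * np.pi / b
    yy = np.abs(y)[..., None]
    zz = z[..., None]
    # cosh(arg·y)/cosh(arg·a/2) in overflow-safe form (all exponents <= 0)
    cosh_ratio = (
        np.exp(arg * (yy - a / 2))
        * (1 + np.exp(-2 * arg * yy))
        / (1 + np.exp(-arg * a))
    )
    terms = sign / odd**3 * (1 - cosh_ratio) * np.cos(arg * zz)
    v = 4 * b**2 / (profile.dynamic_viscosity * np.pi**3) * profile._gradient() * terms.sum(axis=-1)
    return v if v.shape else float(v)


def max_to_mean_ratio(a: float, b: float, series_terms: int = 100) -> float:
    """V_MAX/V_AVR for an a × b duct — 2.0962 square, → 1.5 plate limit."""
    profile = DuctProfile(
        width=a, height=b, dynamic_viscosity=1.0,
        pressure_gradient=1.0, series_terms=series_terms,
    )
    v_max = duct_velocity(profile, 0.0, 0.0)
    return v_max / profile.mean_velocity()


def centerline_velocity(q_total: float, a: float, b: float,
                        series_terms: int = 100) -> float:
    """Centerline (focused-core) velocity for total rate q_total (m/s)."""
    if q_total <= 0:
        raise ValueError("flow rate must be strictly positive")
    return max_to_mean_ratio(a, b, series_terms) * q_total / (a * b)
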