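"""Domain types and the right-hand side of the 18-compartment gut model.

The model tracks glucoraphanin (GR) and sulforaphane (SR) concentrations
through mouth, stomach (2 compartments), small intestine (duodenum + 6),
large intestine (7), and blood, plus cumulative sinks for mouth nitrile,
gut erucin/nitrile, urinary SR and fecal loss.

State vector layout (see :class:`StateLayout`)::

    [ GR: mouth, stomach1, stomach2, duodenum, SI1..SI6, LI1..LI7 ]   17
    [ SR: same order ]                                                17
    blood SR (uM)                                                      1
    mouth nitrile (uM, mouth volume)                                   1
    gut erucin/nitrile (uM, total LI volume)                           1
    cumulative urinary SR (umol)                                       1
    cumulative fecal GR+SR loss (umol)                                 1
                                                                 -> 39

All concentrations are uM, rates min^-1, volumes L, amounts umol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

__all__ = [
    "ProductSpec",
    "MouthKinetics",
    "TransitParams",
    "AbsorptionElimination",
    "GutConversion",
    "CompartmentLayout",
    "ModelParams",
    "StateLayout",
    "gastric_rate_constant",
    "mouth_hydrolysis_rate",
    "mouth_split",
    "transfer_rate",
    "gut_conversion_rates",
    "rhs",
    "make_rhs",
    "make_jacobian",
    "initial_state",
    "total_amount",
    "update_params",
    "PARAMETER_PATHS",
]


class DomainError(ValueError):
    """A value violates a documented precondition."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise DomainError(msg)


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProductSpec:
    """Composition of one broccoli product dose.

    Attributes
    ----------
    name : product label (e.g. ``HighBP``)
    myr : myrosinase content, mg MYR per mg dry broccoli
    cgl0 : initial glucoraphanin concentration in the mouth, uM
    itc0 : initial sulforaphane concentration in the mouth, uM
    br : dry broccoli mass consumed, mg
    """

    name: str
    myr: float
    cgl0: float
    itc0: float
    br: float = 5000.0

    def __post_init__(self) -> None:
        _require(bool(self.name), "product name must be non-empty")
        for f in ("myr", "cgl0", "itc0", "br"):
            _require(getattr(self, f) >= 0, f"{f} must be >= 0")


@dataclass(frozen=True)
class MouthKinetics:
    """Substrate-inhibited Michaelis-Menten hydrolysis in the mouth.

    ``vmax`` umol/(min*mg MYR), ``km``/``ki`` uM, ``srr`` the fraction of
    hydrolysed glucoraphanin that becomes sulforaphane (rest -> nitrile).
    """

    vmax: float = 2070.0
    km: float = 110.2
    ki: float = 893.0
    srr: float = 0.5

    def __post_init__(self) -> None:
        for f in ("vmax", "km", "ki"):
            _require(getattr(self, f) > 0, f"{f} must be > 0")
        _require(0.0 <= self.srr <= 1.0, "srr must be in [0, 1]")


@dataclass(frozen=True)
class TransitParams:
    """First-order transit rate constants (min^-1) and gastric emptying time."""

    k_mouth: float = 30.0
    k_sh: float = 0.025
    st: float = 30.0
    k_tsi: float = 0.018
    k_tli: float = 0.004

    def __post_init__(self) -> None:
        for f in ("k_mouth", "k_sh", "st", "k_tsi", "k_tli"):
            _require(getattr(self, f) > 0, f"{f} must be > 0")


@dataclass(frozen=True)
class AbsorptionElimination:
    """Absorption into and elimination from the blood compartment.

    ``k_a`` may alternatively be given via effective permeability and
    intestinal radius as ``2 * p_eff / radius``; when both routes are
    supplied they must agree.
    """

    k_a: float = 0.180
    k_e: float = 0.02
    p_eff: float | None = None
    radius: float | None = None

    def __post_init__(self) -> None:
        _require(self.k_a >= 0, "k_a must be >= 0")
        _require(self.k_e >= 0, "k_e must be >= 0")
        if self.p_eff is not None and self.radius is not None:
            _require(self.radius > 0, "radius must be > 0")
            implied = 2.0 * self.p_eff / self.radius
            _require(
                math.isclose(self.k_a, implied, rel_tol=1e-9, abs_tol=1e-12),
                f"k_a={self.k_a} inconsistent with 2*p_eff/radius={implied}",
            )


@dataclass(frozen=True)
class GutConversion:
    """Microbial conversion of GR in the large intestine.

    ``k_f`` GR -> SR, ``k_eni`` GR -> erucin/nitrile (both min^-1).
    """

    k_f: float = 0.0033
    k_eni: float = 0.0015

    def __post_init__(self) -> None:
        _require(self.k_f >= 0, "k_f must be >= 0")
        _require(self.k_eni >= 0, "k_eni must be >= 0")


@dataclass(frozen=True)
class CompartmentLayout:
    """Compartment volumes (L) and intestinal segmentation."""

    v_mouth: float = 0.096
    v_stomach1: float = 0.05
    v_stomach2: float = 0.15
    v_duodenum: float = 0.2
    v_si_total: float = 1.5
    n_si: int = 6
    v_li_total: float = 3.4
    n_li: int = 7
    v_blood: float = 5.0

    def __post_init__(self) -> None:
        for f in (
            "v_mouth",
            "v_stomach1",
            "v_stomach2",
            "v_duodenum",
            "v_si_total",
            "v_li_total",
            "v_blood",
        ):
            _require(getattr(self, f) > 0, f"{f} must be > 0")
        _require(self.n_si >= 1, "n_si must be >= 1")
        _require(self.n_li >= 1, "n_li must be >= 1")

    @property
    def v_si(self) -> float:
        """Volume of one post-duodenal small-intestine compartment."""
        return self.v_si_total / self.n_si

    @property
    def v_li(self) -> float:
        """Volume of one large-intestine compartment."""
        return self.v_li_total / self.n_li

    @property
    def n_compartments(self) -> int:
        """Mouth + 2 stomach + (duodenum + n_si) + n_li + blood."""
        return 1 + 2 + 1 + self.n_si + self.n_li + 1


@dataclass(frozen=True)
class ModelParams:
    """Aggregate of all model parameters."""

    product: ProductSpec
    mouth: MouthKinetics = field(default_factory=MouthKinetics)
    transit: TransitParams = field(default_factory=TransitParams)
    absorb: AbsorptionElimination = field(default_factory=AbsorptionElimination)
    gut: GutConversion = field(default_factory=GutConversion)
    layout: CompartmentLayout = field(default_factory=CompartmentLayout)


# Dotted paths used to overlay scalar overrides onto a ModelParams tree.
PARAMETER_PATHS: dict[str, tuple[str, str]] = {
    "myr": ("product", "myr"),
    "cgl0": ("product", "cgl0"),
    "itc0": ("product", "itc0"),
    "br": ("product", "br"),
    "vmax": ("mouth", "vmax"),
    "km": ("mouth", "km"),
    "ki": ("mouth", "ki"),
    "srr": ("mouth", "srr"),
    "k_mouth": ("transit", "k_mouth"),
    "k_sh": ("transit", "k_sh"),
    "st": ("transit", "st"),
    "k_tsi": ("transit", "k_tsi"),
    "k_tli": ("transit", "k_tli"),
    "k_a": ("absorb", "k_a"),
    "k_e": ("absorb", "k_e"),
    "k_f": ("gut", "k_f"),
    "k_eni": ("gut", "k_eni"),
    "v_mouth": ("layout", "v_mouth"),
    "v_stomach1": ("layout", "v_stomach1"),
    "v_stomach2": ("layout", "v_stomach2"),
    "v_duodenum": ("layout", "v_duodenum"),
    "v_si_total": ("layout", "v_si_total"),
    "v_li_total": ("layout", "v_li_total"),
    "v_blood": ("layout", "v_blood"),
}


def update_params(params: ModelParams, **overrides: float) -> ModelParams:
    """Return a copy of ``params`` with named scalar fields replaced.

    Keys are flat symbol names (``srr``, ``k_tsi``, ``v_blood``, ...) mapped
    through :data:`PARAMETER_PATHS`.
    """
    groups: dict[str, dict[str, float]] = {}
    for name, value in overrides.items():
        if name not in PARAMETER_PATHS:
            raise KeyError(f"unknown parameter {name!r}")
        sub, attr = PARAMETER_PATHS[name]
        groups.setdefault(sub, {})[attr] = float(value)
    changes = {
        sub: replace(getattr(params, sub), **fields) for sub, fields in groups.items()
    }
    return replace(params, **changes)


# ---------------------------------------------------------------------------
# Rate laws
# ---------------------------------------------------------------------------


def gastric_rate_constant(st: float) -> float:
    """First-order constant leaving 5% of stomach-2 content after ``st`` min."""
    _require(st > 0, "stomach emptying time must be > 0")
    return -math.log(0.05) / st


def mouth_hydrolysis_rate(
    c_gl: float, mouth: MouthKinetics, product: ProductSpec
) -> float:
    """Magnitude of the substrate-inhibited hydrolysis rate in the mouth (uM/min).

    ``vmax * myr * br * c / (km + c + c^2/ki)``; the caller applies the
    negative sign on the glucoraphanin pool.
    """
    _require(c_gl >= 0, "c_gl must be >= 0")
    num = mouth.vmax * product.myr * product.br * c_gl
    den = mouth.km + c_gl + c_gl * c_gl / mouth.ki
    return num / den


def mouth_split(hydrolysis_rate: float, srr: float) -> tuple[float, float]:
    """Split the hydrolysis flux into (sulforaphane, nitrile) formation rates."""
    _require(0.0 <= srr <= 1.0, "srr must be in [0, 1]")
    _require(hydrolysis_rate >= 0, "hydrolysis_rate must be >= 0")
    return srr * hydrolysis_rate, (1.0 - srr) * hydrolysis_rate


def transfer_rate(
    c_upstream: float, k: float, v_upstream: float, v_downstream: float
) -> float:
    """Concentration inflow rate into the downstream compartment (uM/min).

    The matching upstream outflow is ``k * c_upstream`` (no volume ratio),
    so the transferred amount (concentration x volume) is conserved.
    """
    _require(v_upstream > 0 and v_downstream > 0, "volumes must be > 0")
    _require(k >= 0, "k must be >= 0")
    _require(c_upstream >= 0, "c_upstream must be >= 0")
    return k * (v_upstream / v_downstream) * c_upstream


def gut_conversion_rates(
    c_gl: float, gut: GutConversion
) -> tuple[float, float, float]:
    """Microbial (SR formation, erucin/nitrile formation, GR loss) rates."""
    _require(c_gl >= 0, "c_gl must be >= 0")
    sr = gut.k_f * c_gl
    eni = gut.k_eni * c_gl
    return sr, eni, sr + eni


# ---------------------------------------------------------------------------
# State layout and the assembled ODE right-hand side
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StateLayout:
    """Index bookkeeping for the flat state vector of a given layout."""

    n_gut: int  # gut compartments holding both species

    @classmethod
    def from_layout(cls, layout: CompartmentLayout) -> "StateLayout":
        return cls(n_gut=3 + 1 + layout.n_si + layout.n_li)

    @property
    def gl(self) -> slice:
        return slice(0, self.n_gut)

    @property
    def itc(self) -> slice:
        return slice(self.n_gut, 2 * self.n_gut)

    @property
    def blood(self) -> int:
        return 2 * self.n_gut

    @property
    def mouth_nitrile(self) -> int:
        return 2 * self.n_gut + 1

    @property
    def gut_eni(self) -> int:
        return 2 * self.n_gut + 2

    @property
    def urine(self) -> int:
        return 2 * self.n_gut + 3

    @property
    def fecal(self) -> int:
        return 2 * self.n_gut + 4

    @property
    def size(self) -> int:
        return 2 * self.n_gut + 5


def _gut_volumes(layout: CompartmentLayout) -> np.ndarray:
    return np.concatenate(
        [
            [layout.v_mouth, layout.v_stomach1, layout.v_stomach2, layout.v_duodenum],
            np.full(layout.n_si, layout.v_si),
            np.full(layout.n_li, layout.v_li),
        ]
    )


def _gut_outflow_rates(params: ModelParams) -> np.ndarray:
    t = params.transit
    lay = params.layout
    s = gastric_rate_constant(t.st)
    return np.concatenate(
        [
            [t.k_mouth, t.k_sh, s],
            np.full(1 + lay.n_si, t.k_tsi),  # duodenum + post-duodenal SI
            np.full(lay.n_li, t.k_tli),
        ]
    )


def initial_state(params: ModelParams) -> np.ndarray:
    """Dose placed in the mouth compartment, everything else empty."""
    sl = StateLayout.from_layout(params.layout)
    y0 = np.zeros(sl.size)
    y0[0] = params.product.cgl0
    y0[sl.n_gut] = params.product.itc0
    return y0


def total_amount(y: np.ndarray, params: ModelParams) -> float:
    """Volume-weighted total GR-equivalent amount (umol) across every pool."""
    sl = StateLayout.from_layout(params.layout)
    vols = _gut_volumes(params.layout)
    lay = params.layout
    y = np.asarray(y, dtype=float)
    return float(
        y[..., sl.gl] @ vols
        + y[..., sl.itc] @ vols
        + y[..., sl.blood] * lay.v_blood
        + y[..., sl.mouth_nitrile] * lay.v_mouth
        + y[..., sl.gut_eni] * lay.v_li_total
        + y[..., sl.urine]
        + y[..., sl.fecal]
    )


def make_rhs(params: ModelParams) -> Callable[[float, np.ndarray], np.ndarray]:
    """Precompile the ODE right-hand side for one parameter set.

    Coefficients are bound once so the returned callable is cheap enough
    for repeated solver invocation during fitting.
    """
    lay = params.layout
    sl = StateLayout.from_layout(lay)
    n = sl.n_gut
    vols = _gut_volumes(lay)
    k_out = _gut_outflow_rates(params)
    # inflow coefficient into compartment i+1 from i
    vol_ratio = vols[:-1] / vols[1:]
    k_in = k_out[:-1] * vol_ratio

    li0 = 4 + lay.n_si  # index of first LI compartment
    k_a = params.absorb.k_a
    k_e = params.absorb.k_e
    k_f = params.gut.k_f
    k_eni = params.gut.k_eni
    v_blood = lay.v_blood
    v_li = lay.v_li
    v_li_total = lay.v_li_total
    v_mouth = lay.v_mouth
    srr = params.mouth.srr
    mouth = params.mouth
    product = params.product
    vmax_eff = mouth.vmax * product.myr * product.br
    km, ki = mouth.km, mouth.ki
    k_tli = params.transit.k_tli

    # absorption only in post-duodenal SI and all LI compartments
    absorb = np.zeros(n)
    absorb[4:] = k_a
    absorb_to_blood = absorb * vols / v_blood

    def rhs_fn(t: float, y: np.ndarray) -> np.ndarray:
        c_gl = y[:n]
        c_itc = y[n : 2 * n]
        dy = np.empty_like(y)
        d_gl = dy[:n]
        d_itc = dy[n : 2 * n]

        # first-order transit chain, volume ratio on every inflow
        np.multiply(k_out, c_gl, out=d_gl)
        np.negative(d_gl, out=d_gl)
        d_gl[1:] += k_in * c_gl[:-1]
        np.multiply(k_out, c_itc, out=d_itc)
        np.negative(d_itc, out=d_itc)
        d_itc[1:] += k_in * c_itc[:-1]

        # mouth hydrolysis (clamped substrate) split into SR and nitrile
        c0 = c_gl[0] if c_gl[0] > 0.0 else 0.0
        hyd = vmax_eff * c0 / (km + c0 + c0 * c0 / ki)
        d_gl[0] -= hyd
        d_itc[0] += srr * hyd
        dy[sl.mouth_nitrile] = (1.0 - srr) * hyd

        # microbial conversion in the large intestine (clamped substrate)
        c_gl_li = np.maximum(c_gl[li0:], 0.0)
        d_gl[li0:] -= (k_f + k_eni) * c_gl_li
        d_itc[li0:] += k_f * c_gl_li
        dy[sl.gut_eni] = k_eni * np.sum(c_gl_li) * v_li / v_li_total

        # SR absorption, blood turnover, urinary excretion
        d_itc -= absorb * c_itc
        c_blood = y[sl.blood]
        dy[sl.blood] = absorb_to_blood @ c_itc - k_e * c_blood
        dy[sl.urine] = k_e * c_blood * v_blood

        # distal LI outflow leaves the gut as fecal loss (amount, umol)
        dy[sl.fecal] = k_tli * (c_gl[n - 1] + c_itc[n - 1]) * v_li
        return dy

    return rhs_fn


def make_jacobian(params: ModelParams) -> Callable[[float, np.ndarray], np.ndarray]:
    """Analytic state Jacobian of the right-hand side.

    Everything except the mouth hydrolysis is linear, so the matrix is
    precomputed once and only the three hydrolysis entries depend on the
    state.  Substrate clamping makes those entries zero for negative
    substrate, matching :func:`make_rhs`.
    """
    lay = params.layout
    sl = StateLayout.from_layout(lay)
    n = sl.n_gut
    vols = _gut_volumes(lay)
    k_out = _gut_outflow_rates(params)
    k_in = k_out[:-1] * (vols[:-1] / vols[1:])
    li0 = 4 + lay.n_si
    k_a, k_e = params.absorb.k_a, params.absorb.k_e
    k_f, k_eni = params.gut.k_f, params.gut.k_eni
    v_li, v_li_total, v_blood = lay.v_li, lay.v_li_total, lay.v_blood
    mouth, product = params.mouth, params.product
    srr = mouth.srr
    vmax_eff = mouth.vmax * product.myr * product.br
    km, ki = mouth.km, mouth.ki
    k_tli = params.transit.k_tli

    A = np.zeros((sl.size, sl.size))
    for block in (0, n):  # transit chain, both species
        idx = np.arange(n)
        A[block + idx, block + idx] -= k_out
        A[block + idx[1:], block + idx[:-1]] += k_in
    gl_li = np.arange(li0, n)
    A[gl_li, gl_li] -= k_f + k_eni
    A[n + gl_li, gl_li] += k_f
    A[sl.gut_eni, gl_li] += k_eni * v_li / v_li_total
    itc_abs = np.arange(n + 4, 2 * n)
    A[itc_abs, itc_abs] -= k_a
    A[sl.blood, itc_abs] += k_a * vols[4:] / v_blood
    A[sl.blood, sl.blood] -= k_e
    A[sl.urine, sl.blood] += k_e * v_blood
    A[sl.fecal, n - 1] += k_tli * v_li
    A[sl.fecal, 2 * n - 1] += k_tli * v_li

    def jac_fn(t: float, y: np.ndarray) -> np.ndarray:
        J = A.copy()
        c0 = y[0]
        if c0 > 0.0 and vmax_eff > 0.0:
            den = km + c0 + c0 * c0 / ki
            dh = vmax_eff * (km - c0 * c0 / ki) / (den * den)
            J[0, 0] -= dh
            J[n, 0] += srr * dh
            J[sl.mouth_nitrile, 0] += (1.0 - srr) * dh
        return J

    return jac_fn


def rhs(t: float, state: np.ndarray, params: ModelParams) -> np.ndarray:
    """Full model derivative at ``(t, state)``.

    Convenience wrapper around :func:`make_rhs`; use the factory directly
    when calling repeatedly with the same parameters.
    """
    state = np.asarray(state, dtype=float)
    expected = StateLayout.from_layout(params.layout).size
    if state.shape != (expected,):
        raise ValueError(
            f"state has shape {state.shape}, expected ({expected},) for this layout"
        )
    return make_rhs(params)(t, state)
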