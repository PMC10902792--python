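"""Monte Carlo random-walk transport of fluorescence photons in a turbid slab.

The medium is a homogeneous semi-infinite slab (unbounded laterally and in
depth, bounded above by the tissue--air interface at z = 0).  A fluorophore
at depth ``z`` is treated as an isotropic point emitter; excitation photons
are not modelled.  Each emitted photon performs a hop/fate/spin random walk:

* hop      -- exponential step length with attenuation mu_t = mu_a + mu_s,
* fate     -- at each interaction the photon is absorbed with probability
              mu_a / mu_t, otherwise it scatters,
* spin     -- the scattering deflection follows the Henyey--Greenstein phase
              function with mean cosine ``g``.

A photon whose hop crosses the z = 0 plane is advanced exactly to the plane;
there an unpolarized Fresnel test (with total internal reflection) decides
whether it escapes into air (n = 1) or is specularly reflected back into
the medium.  Photons are whole: no packet weights, no roulette.

Lengths are in cm and attenuation coefficients in 1/cm throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "TissueOptics",
    "SourcePosition",
    "PhotonFate",
    "OUTCOME_ABSORBED",
    "OUTCOME_ESCAPED",
    "OUTCOME_TRUNCATED",
    "sample_isotropic_direction",
    "sample_step_length",
    "sample_hg_deflection",
    "fresnel_reflectance",
    "fresnel_transmit",
    "propagate_photon",
    "propagate_batch",
]

OUTCOME_ABSORBED = 0
OUTCOME_ESCAPED = 1
OUTCOME_TRUNCATED = 2

#: hard cap on interactions per photon; guarantees termination when mu_a = 0
DEFAULT_MAX_EVENTS = 1_000_000


@dataclass(frozen=True)
class TissueOptics:
    """Optical properties of the homogeneous medium.

    Defaults mimic highly pigmented skin / piglet tissue at ~800 nm:
    n = 1.4, mu_a = 0.4 /cm, mu_s = 300 /cm, g = 0.96.
    """

    n: float = 1.4
    mu_a: float = 0.4
    mu_s: float = 300.0
    g_hg: float = 0.96
    fresnel_boundary: bool = True
    max_events: int = DEFAULT_MAX_EVENTS

    def __post_init__(self) -> None:
        if self.mu_a < 0 or self.mu_s < 0:
            raise ValueError("mu_a and mu_s must be non-negative")
        if self.mu_a + self.mu_s <= 0:
            raise ValueError("total attenuation mu_a + mu_s must be positive")
        if self.n < 1:
            raise ValueError("refractive index must be >= 1")
        if abs(self.g_hg) > 1:
            raise ValueError("anisotropy g must lie in [-1, 1]")

    @property
    def mu_t(self) -> float:
        return self.mu_a + self.mu_s

    @property
    def albedo(self) -> float:
        return self.mu_s / self.mu_t

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mu_a_percm": self.mu_a,
            "mu_s_percm": self.mu_s,
            "g": self.g_hg,
            "fresnel_boundary": self.fresnel_boundary,
            "max_events": self.max_events,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TissueOptics":
        return cls(
            n=d.get("n", 1.4),
            mu_a=d.get("mu_a_percm", 0.4),
            mu_s=d.get("mu_s_percm", 300.0),
            g_hg=d.get("g", 0.96),
            fresnel_boundary=d.get("fresnel_boundary", True),
            max_events=d.get("max_events", DEFAULT_MAX_EVENTS),
        )


@dataclass(frozen=True)
class SourcePosition:
    """Source location: lateral (x, y) relative to the detector center and
    depth z >= 0 measured from the tissue surface into the medium."""

    x: float = 0.0
    y: float = 0.0
    z: float = 0.0

    def __post_init__(self) -> None:
        if self.z < 0:
            raise ValueError("source depth z must be >= 0")


@dataclass(frozen=True)
class PhotonFate:
    """Terminal record of one photon walk."""

    outcome: int  # OUTCOME_ABSORBED | OUTCOME_ESCAPED | OUTCOME_TRUNCATED
    exit_x: float
    exit_y: float
    path_length: float
    n_scatter_events: int

    @property
    def escaped(self) -> bool:
        return self.outcome == OUTCOME_ESCAPED


def sample_isotropic_direction(rng: np.random.Generator) -> np.ndarray:
    """Draw a unit vector uniformly distributed on the sphere."""
    uz = 2.0 * rng.random() - 1.0
    phi = 2.0 * math.pi * rng.random()
    sint = math.sqrt(max(0.0, 1.0 - uz * uz))
    return np.array([sint * math.cos(phi), sint * math.sin(phi), uz])


def sample_step_length(optics: TissueOptics, rng: np.random.Generator) -> float:
    """Exponential free path: step = -ln(xi) / mu_t, xi ~ U(0, 1]."""
    xi = 1.0 - rng.random()  # in (0, 1]
    return -math.log(xi) / optics.mu_t


def sample_hg_deflection(g_hg: float, rng: np.random.Generator) -> tuple[float, float]:
    """Sample (cos_theta, phi) of a single scattering event.

    cos_theta follows the Henyey--Greenstein distribution with mean cosine
    ``g_hg``; the azimuth phi is uniform on [0, 2*pi).
    """
    if abs(g_hg) > 1:
        raise ValueError("anisotropy g must lie in [-1, 1]")
    xi = rng.random()
    if abs(g_hg) < 1e-12:
        cost = 2.0 * xi - 1.0
    else:
        tmp = (1.0 - g_hg * g_hg) / (1.0 - g_hg + 2.0 * g_hg * xi)
        cost = (1.0 + g_hg * g_hg - tmp * tmp) / (2.0 * g_hg)
        cost = min(1.0, max(-1.0, cost))
    phi = 2.0 * math.pi * rng.random()
    return cost, phi


def fresnel_reflectance(cos_incidence: float, n_in: float, n_out: float) -> float:
    """Unpolarized Fresnel reflectance for incidence from ``n_in`` to ``n_out``.

    Returns 1.0 beyond the critical angle (total internal reflection).
    """
    if not 0.0 <= cos_incidence <= 1.0:
        raise ValueError("cos_incidence must lie in [0, 1]")
    if n_in == n_out:
        return 0.0
    ci = cos_incidence
    sin_i = math.sqrt(max(0.0, 1.0 - ci * ci))
    sin_t = n_in / n_out * sin_i
    if sin_t >= 1.0:
        return 1.0
    ct = math.sqrt(1.0 - sin_t * sin_t)
    rs = (n_in * ci - n_out * ct) / (n_in * ci + n_out * ct)
    rp = (n_in * ct - n_out * ci) / (n_in * ct + n_out * ci)
    return 0.5 * (rs * rs + rp * rp)


def fresnel_transmit(
    cos_incidence: float,
    n_in: float,
    n_out: float,
    rng: np.random.Generator,
) -> bool:
    """Bernoulli boundary test: True if the photon is transmitted."""
    return rng.random() >= fresnel_reflectance(cos_incidence, n_in, n_out)


def propagate_photon(
    src: SourcePosition, optics: TissueOptics, rng: np.random.Generator
) -> PhotonFate:
    """Walk a single photon until it is absorbed, escapes, or is truncated.

    Pure-Python reference path built from the scalar sampling operations;
    :func:`propagate_batch` is the vectorised production equivalent.
    """
    if src.z == 0.0:
        # degenerate surface source: escapes immediately at its own position
        return PhotonFate(OUTCOME_ESCAPED, src.x, src.y, 0.0, 0)

    x, y, z = src.x, src.y, src.z
    ux, uy, uz = sample_isotropic_direction(rng)
    path = 0.0
    n_scatter = 0
    for _ in range(optics.max_events):
        step = sample_step_length(optics, rng)
        if uz < 0.0 and z + uz * step <= 0.0:
            # advance exactly to the surface and apply the boundary rule
            s_surf = -z / uz
            x += ux * s_surf
            y += uy * s_surf
            path += s_surf
            z = 0.0
            cos_inc = -uz
            transmitted = (not optics.fresnel_boundary) or fresnel_transmit(
                cos_inc, optics.n, 1.0, rng
            )
            if transmitted:
                return PhotonFate(OUTCOME_ESCAPED, x, y, path, n_scatter)
            uz = -uz  # specular reflection; fresh exponential step (memoryless)
            continue
        x += ux * step
        y += uy * step
        z += uz * step
        path += step
        if rng.random() < optics.mu_a / optics.mu_t:
            return PhotonFate(OUTCOME_ABSORBED, math.nan, math.nan, path, n_scatter)
        cost, phi = sample_hg_deflection(optics.g_hg, rng)
        ux, uy, uz = _spin(ux, uy, uz, cost, phi)
        n_scatter += 1
    return PhotonFate(OUTCOME_TRUNCATED, math.nan, math.nan, path, n_scatter)


def _spin(ux, uy, uz, cost, phi):
    """Rotate the direction vector by polar angle acos(cost), azimuth phi."""
    sint = math.sqrt(max(0.0, 1.0 - cost * cost))
    cosp = math.cos(phi)
    sinp = math.sin(phi)
    if abs(uz) > 0.99999:
        return sint * cosp, sint * sinp, cost * (1.0 if uz >= 0 else -1.0)
    denom = math.sqrt(1.0 - uz * uz)
    nux = sint * (ux * uz * cosp - uy * sinp) / denom + ux * cost
    nuy = sint * (uy * uz * cosp + ux * sinp) / denom + uy * cost
    nuz = -sint * cosp * denom + uz * cost
    norm = math.sqrt(nux * nux + nuy * nuy + nuz * nuz)
    return nux / norm, nuy / norm, nuz / norm


@njit(cache=True, inline="always")
def _xorshift(state):
    """xorshift64* stream; returns a uniform double in [0, 1)."""
    s = state[0]
    s ^= s >> np.uint64(12)
    s ^= s << np.uint64(25)
    s ^= s >> np.uint64(27)
    state[0] = s
    bits = (s * np.uint64(2685821657736338717)) >> np.uint64(11)
    return float(bits) * (1.0 / 9007199254740992.0)


@njit(cache=True, fastmath=True)
def _walk_kernel(
    n_photons,
    x0,
    y0,
    z0,
    mu_a,
    mu_t,
    g,
    n_tissue,
    fresnel_on,
    max_events,
    seed,
):  # pragma: no cover - exercised through propagate_batch
    # splitmix64 scramble of the seed initialises the xorshift64* state
    state = np.empty(1, dtype=np.uint64)
    zmix = (np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    zmix = (zmix ^ (zmix >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    zmix = (zmix ^ (zmix >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    zmix = zmix ^ (zmix >> np.uint64(31))
    if zmix == np.uint64(0):
        zmix = np.uint64(0x1234567887654321)
    state[0] = zmix
    outcome = np.empty(n_photons, dtype=np.int8)
    exit_x = np.full(n_photons, np.nan)
    exit_y = np.full(n_photons, np.nan)
    path_len = np.zeros(n_photons)
    n_scat = np.zeros(n_photons, dtype=np.int64)
    p_abs = mu_a / mu_t
    crit_cos = 0.0
    if n_tissue > 1.0:
        crit_cos = math.sqrt(1.0 - 1.0 / (n_tissue * n_tissue))
    for i in range(n_photons):
        if z0 == 0.0:
            outcome[i] = OUTCOME_ESCAPED
            exit_x[i] = x0
            exit_y[i] = y0
            continue
        x = x0
        y = y0
        z = z0
        uz = 2.0 * _xorshift(state) - 1.0
        phi0 = 2.0 * math.pi * _xorshift(state)
        st = math.sqrt(max(0.0, 1.0 - uz * uz))
        ux = st * math.cos(phi0)
        uy = st * math.sin(phi0)
        path = 0.0
        scat = 0
        fate = OUTCOME_TRUNCATED
        for _ in range(max_events):
            step = -math.log(1.0 - _xorshift(state)) / mu_t
            if uz < 0.0 and z + uz * step <= 0.0:
                s_surf = -z / uz
                x += ux * s_surf
                y += uy * s_surf
                path += s_surf
                z = 0.0
                cos_inc = -uz
                refl = 0.0
                if fresnel_on:
                    sin_i = math.sqrt(max(0.0, 1.0 - cos_inc * cos_inc))
                    sin_t = n_tissue * sin_i
                    if sin_t >= 1.0:
                        refl = 1.0
                    else:
                        ct = math.sqrt(1.0 - sin_t * sin_t)
                        rs = (n_tissue * cos_inc - ct) / (n_tissue * cos_inc + ct)
                        rp = (n_tissue * ct - cos_inc) / (n_tissue * ct + cos_inc)
                        refl = 0.5 * (rs * rs + rp * rp)
                if refl == 0.0 or _xorshift(state) >= refl:
                    fate = OUTCOME_ESCAPED
                    break
                uz = -uz
                continue
            x += ux * step
            y += uy * step
            z += uz * step
            path += step
            if _xorshift(state) < p_abs:
                fate = OUTCOME_ABSORBED
                break
            # Henyey-Greenstein spin
            xi = _xorshift(state)
            if abs(g) < 1e-12:
                cost = 2.0 * xi - 1.0
            else:
                tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
                cost = (1.0 + g * g - tmp * tmp) / (2.0 * g)
                if cost > 1.0:
                    cost = 1.0
                elif cost < -1.0:
                    cost = -1.0
            phi = 2.0 * math.pi * _xorshift(state)
            sint = math.sqrt(max(0.0, 1.0 - cost * cost))
            cosp = math.cos(phi)
            sinp = math.sin(phi)
            if abs(uz) > 0.99999:
                ux = sint * cosp
                uy = sint * sinp
                uz = cost if uz >= 0 else -cost
            else:
                denom = math.sqrt(1.0 - uz * uz)
                nux = sint * (ux * uz * cosp - uy * sinp) / denom + ux * cost
                nuy = sint * (uy * uz * cosp + ux * sinp) / denom + uy * cost
                nuz = -sint * cosp * denom + uz * cost
                norm = math.sqrt(nux * nux + nuy * nuy + nuz * nuz)
                ux = nux / norm
                uy = nuy / norm
                uz = nuz / norm
            scat += 1
        outcome[i] = fate
        if fate == OUTCOME_ESCAPED:
            exit_x[i] = x
            exit_y[i] = y
        path_len[i] = path
        n_scat[i] = scat
    return outcome, exit_x, exit_y, path_len, n_scat


def propagate_batch(
    n_photons: int,
    src: SourcePosition,
    optics: TissueOptics,
    seed: int,
) -> dict[str, np.ndarray]:
    """Propagate ``n_photons`` independent photons from one source.

    Returns a dict of per-photon arrays: ``outcome`` (int8 codes),
    ``exit_x``/``exit_y`` (cm; NaN unless escaped), ``path_length`` (cm)
    and ``n_scatter`` (counts).  Deterministic for a given ``seed``.
    """
    if n_photons < 0:
        raise ValueError("n_photons must be >= 0")
    outcome, ex, ey, pl, ns = _walk_kernel(
        int(n_photons),
        float(src.x),
        float(src.y),
        float(src.z),
        float(optics.mu_a),
        float(optics.mu_t),
        float(optics.g_hg),
        float(optics.n),
        bool(optics.fresnel_boundary),
        int(optics.max_events),
        int(seed) % (2**32 - 1),
    )
    return {
        "outcome": outcome,
        "exit_x": ex,
        "exit_y": ey,
        "path_length": pl,
        "n_scatter": ns,
    }
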