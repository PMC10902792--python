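"""Emission photophysics and the time-gated pixelated detector model.

The forward model samples the fluorophore's mono-exponential decay at the
gate times ``t_k = (k - 1) * g_s`` (gate width is zero: each gate is a point
sample of the decay curve).  The number of photons emitted at gate k is

    N(t_k) = round(A * exp(-t_k / tau)),   A = round(a * QY),

where ``a`` is the initial photon budget and QY the fluorescence quantum
yield.  Every emitted photon is propagated through the medium
(:mod:`turbiflim.transport`); photons that escape through the surface inside
the detector footprint are thinned by the detector's photon efficiency
(Bernoulli per photon) and binned into the pixel enclosing their exit point.

Gate assignment deliberately ignores in-tissue time of flight: a photon
emitted at decay sample ``t_k`` is always recorded in gate k.  Time of
flight is available per photon for diagnostics only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .transport import (
    OUTCOME_ABSORBED,
    OUTCOME_ESCAPED,
    OUTCOME_TRUNCATED,
    SourcePosition,
    TissueOptics,
    propagate_batch,
)

__all__ = [
    "FluorophoreSource",
    "GateConfig",
    "DetectorConfig",
    "GateStack",
    "emission_counts",
    "simulate_gate_stack",
    "total_intensity_image",
]


@dataclass(frozen=True)
class FluorophoreSource:
    """A point fluorophore: position, lifetime tau (ns), quantum yield and
    initial photon budget ``a`` (photons at the first decay sample)."""

    position: SourcePosition
    tau: float
    quantum_yield: float
    initial_photons: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("lifetime tau must be > 0")
        if not 0 < self.quantum_yield <= 1:
            raise ValueError("quantum yield must lie in (0, 1]")
        if self.initial_photons < 0:
            raise ValueError("initial photon budget must be >= 0")

    @property
    def pre_exponential(self) -> int:
        """A = round(a * QY), round-half-to-even."""
        return int(np.rint(self.initial_photons * self.quantum_yield))

    def to_dict(self) -> dict:
        return {
            "x": self.position.x,
            "y": self.position.y,
            "z": self.position.z,
            "tau_ns": self.tau,
            "quantum_yield": self.quantum_yield,
            "initial_photons": self.initial_photons,
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FluorophoreSource":
        return cls(
            position=SourcePosition(d.get("x", 0.0), d.get("y", 0.0), d["z"]),
            tau=d["tau_ns"],
            quantum_yield=d["quantum_yield"],
            initial_photons=d["initial_photons"],
            label=d.get("label", ""),
        )


@dataclass(frozen=True)
class GateConfig:
    """Time-gating parameters.

    Defaults follow a 512x512 time-gated SPAD camera driven at 20 MHz:
    G = 117 gates stepped by g_s = 428 ps tile one 50 ns laser period.
    The simulated gate width is zero (point samples of the decay).
    """

    num_gates: int = 117
    gate_step_ps: float = 428.0
    gate_width_ps: float = 0.0
    rep_rate_mhz: float = 20.0

    def __post_init__(self) -> None:
        if self.num_gates < 2:
            raise ValueError("need at least 2 gates")
        if self.gate_step_ps <= 0:
            raise ValueError("gate step must be > 0")
        if self.gate_width_ps < 0:
            raise ValueError("gate width must be >= 0")
        if self.rep_rate_mhz <= 0:
            raise ValueError("repetition rate must be > 0")
        if self.num_gates * self.gate_step_ps > 1e6 / self.rep_rate_mhz + self.gate_step_ps:
            raise ValueError("gates must tile at most one laser period")

    @property
    def period_ns(self) -> float:
        return 1000.0 / self.rep_rate_mhz

    @property
    def gate_times_ns(self) -> np.ndarray:
        """t_k = (k - 1) * g_s in ns, k = 1..G."""
        return np.arange(self.num_gates) * self.gate_step_ps * 1e-3

    def to_dict(self) -> dict:
        return {
            "num_gates": self.num_gates,
            "gate_step_ps": self.gate_step_ps,
            "gate_width_ps": self.gate_width_ps,
            "rep_rate_mhz": self.rep_rate_mhz,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GateConfig":
        return cls(
            num_gates=d["num_gates"],
            gate_step_ps=d["gate_step_ps"],
            gate_width_ps=d.get("gate_width_ps", 0.0),
            rep_rate_mhz=d["rep_rate_mhz"],
        )


@dataclass(frozen=True)
class DetectorConfig:
    """Contact-imaging pixel array on the tissue surface.

    The exit point of an escaping photon maps directly to the enclosing
    pixel (no lens).  Default: 1 x 1 cm, 512 x 512 pixels (19.53 um pitch),
    13% photon efficiency, centered on the origin.
    """

    width_cm: float = 1.0
    height_cm: float = 1.0
    n_px_x: int = 512
    n_px_y: int = 512
    photon_efficiency: float = 0.13
    center_x: float = 0.0
    center_y: float = 0.0

    def __post_init__(self) -> None:
        if self.width_cm <= 0 or self.height_cm <= 0:
            raise ValueError("detector dimensions must be positive")
        if self.n_px_x < 1 or self.n_px_y < 1:
            raise ValueError("pixel counts must be >= 1")
        if not 0 < self.photon_efficiency <= 1:
            raise ValueError("photon efficiency must lie in (0, 1]")

    @property
    def pitch_x(self) -> float:
        return self.width_cm / self.n_px_x

    @property
    def pitch_y(self) -> float:
        return self.height_cm / self.n_px_y

    @property
    def x_min(self) -> float:
        return self.center_x - self.width_cm / 2.0

    @property
    def y_min(self) -> float:
        return self.center_y - self.height_cm / 2.0

    def pixel_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map exit coordinates to (ix, iy) pixel indices and an in-bounds mask."""
        ix = np.floor((np.asarray(x) - self.x_min) / self.pitch_x).astype(np.int64)
        iy = np.floor((np.asarray(y) - self.y_min) / self.pitch_y).astype(np.int64)
        ok = (ix >= 0) & (ix < self.n_px_x) & (iy >= 0) & (iy < self.n_px_y)
        return ix, iy, ok

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        xs = self.x_min + (np.arange(self.n_px_x) + 0.5) * self.pitch_x
        ys = self.y_min + (np.arange(self.n_px_y) + 0.5) * self.pitch_y
        return xs, ys

    def to_dict(self) -> dict:
        return {
            "width_cm": self.width_cm,
            "height_cm": self.height_cm,
            "n_px_x": self.n_px_x,
            "n_px_y": self.n_px_y,
            "photon_efficiency": self.photon_efficiency,
            "center_x": self.center_x,
            "center_y": self.center_y,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DetectorConfig":
        return cls(**d)


@dataclass
class GateStack:
    """Per-gate photon-count images plus all metadata needed to analyse them.

    ``counts`` has shape (G, n_px_y, n_px_x); page k holds the image of gate
    k + 1 (gate order = page order).  ``records`` optionally carries the
    continuous exit coordinates of every detected photon for spot statistics
    (columns: x, y, gate index, source index, path length).
    """

    counts: np.ndarray
    gates: GateConfig
    detector: DetectorConfig
    meta: dict = field(default_factory=dict)
    records: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.counts.ndim != 3:
            raise ValueError("counts must be a (G, ny, nx) array")
        if self.counts.shape[0] != self.gates.num_gates:
            raise ValueError(
                f"stack has {self.counts.shape[0]} pages but the gate "
                f"configuration declares {self.gates.num_gates} gates"
            )

    @property
    def gate_times_ns(self) -> np.ndarray:
        return self.gates.gate_times_ns

    @property
    def num_gates(self) -> int:
        return self.gates.num_gates


def emission_counts(fluor: FluorophoreSource, gates: GateConfig) -> np.ndarray:
    """Photons emitted at each gate sample: N(t_k) = round(A * exp(-t_k/tau)).

    Round-half-to-even keeps the rounding unbiased across gates; the result
    is monotone non-increasing in k.
    """
    a_pre = fluor.pre_exponential
    t = gates.gate_times_ns
    return np.rint(a_pre * np.exp(-t / fluor.tau)).astype(np.int64)


def total_intensity_image(stack: GateStack) -> np.ndarray:
    """Pixelwise sum over all gate pages (the steady-state intensity image)."""
    return stack.counts.sum(axis=0)


def simulate_gate_stack(
    scene: list[FluorophoreSource],
    optics: TissueOptics,
    det: DetectorConfig,
    gates: GateConfig,
    seed: int,
    keep_records: bool = True,
) -> GateStack:
    """Run the full forward model for a scene of point fluorophores.

    For each source, all N(t_k) photons of every gate are propagated through
    the medium; escaped photons landing inside the detector footprint are
    thinned by the photon efficiency and binned into pixels of the gate-k
    page.  Deterministic for a given ``seed``.
    """
    if not scene:
        raise ValueError("scene must contain at least one fluorophore")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(scene))
    shape = (gates.num_gates, det.n_px_y, det.n_px_x)
    counts = np.zeros(shape, dtype=np.uint32)
    rec_x, rec_y, rec_gate, rec_src, rec_path = [], [], [], [], []
    tallies = {"emitted": 0, "absorbed": 0, "escaped": 0, "truncated": 0, "detected": 0}

    for i_src, fluor in enumerate(scene):
        n_per_gate = emission_counts(fluor, gates)
        n_total = int(n_per_gate.sum())
        tallies["emitted"] += n_total
        if n_total == 0:
            continue
        child = child_seeds[i_src]
        walk_seed = int(child.generate_state(1, dtype=np.uint32)[0])
        rng = np.random.default_rng(child)
        res = propagate_batch(n_total, fluor.position, optics, walk_seed)
        outcome = res["outcome"]
        tallies["absorbed"] += int(np.count_nonzero(outcome == OUTCOME_ABSORBED))
        tallies["escaped"] += int(np.count_nonzero(outcome == OUTCOME_ESCAPED))
        tallies["truncated"] += int(np.count_nonzero(outcome == OUTCOME_TRUNCATED))
        gate_of = np.repeat(np.arange(gates.num_gates), n_per_gate)
        esc = outcome == OUTCOME_ESCAPED
        ix, iy, on_det = det.pixel_of(res["exit_x"][esc], res["exit_y"][esc])
        kept = on_det & (rng.random(on_det.size) < det.photon_efficiency)
        g_k = gate_of[esc][kept]
        ix, iy = ix[kept], iy[kept]
        tallies["detected"] += int(kept.sum())
        np.add.at(counts, (g_k, iy, ix), 1)
        if keep_records:
            rec_x.append(res["exit_x"][esc][kept])
            rec_y.append(res["exit_y"][esc][kept])
            rec_gate.append(g_k)
            rec_src.append(np.full(g_k.size, i_src, dtype=np.int32))
            rec_path.append(res["path_length"][esc][kept])

    records = None
    if keep_records:
        records = {
            "x": np.concatenate(rec_x) if rec_x else np.empty(0),
            "y": np.concatenate(rec_y) if rec_y else np.empty(0),
            "gate": np.concatenate(rec_gate) if rec_gate else np.empty(0, dtype=np.int64),
            "source": np.concatenate(rec_src) if rec_src else np.empty(0, dtype=np.int32),
            "path_length": np.concatenate(rec_path) if rec_path else np.empty(0),
        }
    meta = {
        "seed": int(seed),
        "optics": optics.to_dict(),
        "scene": [f.to_dict() for f in scene],
        "tallies": tallies,
    }
    return GateStack(counts=counts, gates=gates, detector=det, meta=meta, records=records)
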