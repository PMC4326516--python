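"""Synthetic multi-echo data with known ground truth.

Two digital phantoms are provided:

* a six-tube relaxometry phantom emulating MnCl2-doped water tubes whose
  T2 values span the myocardium-relevant range and whose T1 is about ten
  times T2 (the behaviour of MnCl2 solution at 1.5 T), and
* a cardiac short-axis phantom: an annular left-ventricular myocardium
  with per-AHA-segment T2, a nulled (black-blood) cavity and no
  epicardial fat signal (fat suppression assumed perfect).

Echo trains are rendered through the slice-profile EPG forward model of
the requested protocol (pure exponential decay for the ``"ideal"``
profile) and corrupted with noncentral-chi magnitude noise, so the
statistics of the generated images match the likelihood used for
fitting.  Generation is fully seeded and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .epg import slice_profile_echo_train
from .fitting import MultiEchoStack
from .noise import NoiseModel, sample_magnitude
from .protocols import GraSEProtocol, echo_times
from .segments import SegmentModel, segment_ids, SEGMENT_NAMES, _LEVEL_OFFSET

__all__ = [
    "PhantomSpec",
    "DEFAULT_TUBE_T2",
    "generate_stack",
    "generate_cardiac",
]

#: Default tube T2 values (ms), spanning healthy myocardium (~50 ms)
#: through acute-edema values (~80-90 ms) with margins on both sides.
DEFAULT_TUBE_T2 = (40.0, 50.0, 55.0, 60.0, 80.0, 120.0)


@dataclass
class PhantomSpec:
    """Ground-truth description of a synthetic phantom acquisition.

    ``snr`` is the first-echo signal-to-noise ratio: the noise scale is
    ``sigma = s0 * exp(-TE_1 / median(T2)) / snr``.  ``t1_rule`` is
    either ``"10x_t2"`` (MnCl2-like solutions) or an explicit T1 in ms.
    """

    kind: str = "tubes"
    t2_values: tuple = DEFAULT_TUBE_T2
    t1_rule: str | float = "10x_t2"
    snr: float = 50.0
    n_channels: int = 1
    s0: float = 100.0
    seed: int = 0
    image_shape: tuple[int, int] | None = None  # default: protocol matrix

    def __post_init__(self) -> None:
        if self.kind not in ("tubes", "cardiac"):
            raise ValueError("kind must be 'tubes' or 'cardiac'")
        if self.snr <= 0 or self.s0 <= 0:
            raise ValueError("snr and s0 must be positive")
        if any(t <= 0 for t in self.t2_values):
            raise ValueError("T2 values must be positive")

    def t1_of(self, t2: float) -> float:
        if self.t1_rule == "10x_t2":
            return 10.0 * t2
        return float(self.t1_rule)

    def sigma(self, protocol: GraSEProtocol) -> float:
        te1 = protocol.first_te
        t2_ref = float(np.median(self.t2_values))
        return self.s0 * np.exp(-te1 / t2_ref) / self.snr


def _tube_layout(shape: tuple[int, int], n_tubes: int) -> list[tuple[float, float, float]]:
    """Centres and radius of ``n_tubes`` tubes in a 2 x ceil(n/2) grid."""
    ny, nx = shape
    n_cols = (n_tubes + 1) // 2
    radius = min(ny / 5.0, nx / (2.5 * n_cols)) * 0.8
    ys = [ny * 0.3, ny * 0.7]
    xs = np.linspace(nx * 0.18, nx * 0.82, n_cols)
    layout = []
    for i in range(n_tubes):
        layout.append((float(xs[i % n_cols]), float(ys[i // n_cols]), radius))
    return layout


def _render(
    label_map: np.ndarray,
    trains: dict[int, np.ndarray],
    spec: PhantomSpec,
    protocol: GraSEProtocol,
) -> tuple[MultiEchoStack, np.ndarray, np.ndarray]:
    """Scale trains by S0, add noncentral-chi noise, build the stack."""
    n_echoes = protocol.n_echoes
    ny, nx = label_map.shape
    clean = np.zeros((n_echoes, ny, nx))
    for lab, train in trains.items():
        clean[:, label_map == lab] = spec.s0 * train[:, None]
    noise = NoiseModel(spec.sigma(protocol), spec.n_channels)
    rng = np.random.default_rng(spec.seed)
    noisy = sample_magnitude(clean, noise, rng)
    stack = MultiEchoStack(
        volumes=noisy,
        echo_times=np.array(echo_times(protocol)),
        noise=noise,
        protocol=protocol,
    )
    t2_truth = np.zeros((ny, nx))
    s0_truth = np.zeros((ny, nx))
    for lab in trains:
        t2 = _label_t2(lab, spec)
        t2_truth[label_map == lab] = t2
        s0_truth[label_map == lab] = spec.s0
    return stack, t2_truth, s0_truth


def _label_t2(lab: int, spec: PhantomSpec) -> float:
    return float(spec.t2_values[lab - 1])


def generate_stack(
    spec: PhantomSpec, protocol: GraSEProtocol
) -> tuple[MultiEchoStack, dict]:
    """Render the six-tube phantom through the forward model.

    Returns the noisy multi-echo stack and a ground-truth dict with keys
    ``label_map`` (0 background, 1..n tubes), ``t2_map``, ``s0_map``,
    ``t2_values`` and ``sigma``.
    """
    if spec.kind != "tubes":
        raise ValueError("generate_stack renders 'tubes' phantoms; see generate_cardiac")
    shape = spec.image_shape or (protocol.matrix_phase, protocol.matrix_read)
    layout = _tube_layout(shape, len(spec.t2_values))
    ny, nx = shape
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny))
    label_map = np.zeros(shape, dtype=int)
    for i, (cx, cy, r) in enumerate(layout, start=1):
        inside = (xs - cx) ** 2 + (ys - cy) ** 2 <= r**2
        if np.any(label_map[inside] != 0):
            raise ValueError("tube geometry overlaps")
        label_map[inside] = i

    trains = {
        i + 1: slice_profile_echo_train(t2, spec.t1_of(t2), protocol)
        for i, t2 in enumerate(spec.t2_values)
    }
    stack, t2_truth, s0_truth = _render(label_map, trains, spec, protocol)
    truth = {
        "label_map": label_map,
        "t2_map": t2_truth,
        "s0_map": s0_truth,
        "t2_values": dict(enumerate(spec.t2_values, start=1)),
        "sigma": stack.noise.sigma,
    }
    return stack, truth


def _circle(cx: float, cy: float, r: float, n: int = 64) -> np.ndarray:
    th = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th)])


def generate_cardiac(
    spec: PhantomSpec,
    protocol: GraSEProtocol,
    segment_t2,
    slice_level: str = "mid",
) -> tuple[MultiEchoStack, SegmentModel, dict]:
    """Render a short-axis cardiac phantom with per-segment T2.

    ``segment_t2`` lists one T2 (ms) per AHA segment of the slice level
    in standard order (6 for basal/mid, 4 for apical).  The myocardium is
    an annulus about the image centre; the blood pool is nulled (black
    blood) and there is no fat signal.  Returns the noisy stack, the
    matching ground-truth :class:`SegmentModel` (64-gon contours + RV
    insertion on the anterior septal junction) and a truth dict.
    """
    segment_t2 = tuple(float(t) for t in segment_t2)
    n_expected = 4 if slice_level == "apical" else 6
    if slice_level not in ("basal", "mid", "apical"):
        raise ValueError("slice_level must be 'basal', 'mid' or 'apical'")
    if len(segment_t2) != n_expected:
        raise ValueError(
            f"{slice_level} slice needs {n_expected} segment T2 values, got {len(segment_t2)}"
        )
    shape = spec.image_shape or (protocol.matrix_phase, protocol.matrix_read)
    ny, nx = shape
    cx, cy = nx / 2.0, ny / 2.0
    r_endo = 0.095 * min(nx, ny)
    r_epi = 0.18 * min(nx, ny)

    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny))
    rr = np.sqrt((xs - cx) ** 2 + (ys - cy) ** 2)
    myo = (rr > r_endo) & (rr <= r_epi)

    # RV insertion at display angle 150 deg (anterior-septal junction,
    # septum image-left); sectors proceed counterclockwise in display.
    phi_rv = 150.0
    phi = np.degrees(np.arctan2(cy - ys, xs - cx)) % 360.0
    if slice_level == "apical":
        rel = (phi - (phi_rv - 15.0)) % 360.0
        sector = np.floor(rel / 90.0).astype(int)
    else:
        rel = (phi - phi_rv) % 360.0
        sector = np.floor(rel / 60.0).astype(int)
    label_map = np.zeros(shape, dtype=int)
    label_map[myo] = sector[myo] + 1  # local 1..n labels for rendering

    spec_local = PhantomSpec(
        kind="cardiac",
        t2_values=segment_t2,
        t1_rule=spec.t1_rule if spec.t1_rule != "10x_t2" else 1000.0,
        snr=spec.snr,
        n_channels=spec.n_channels,
        s0=spec.s0,
        seed=spec.seed,
        image_shape=shape,
    )
    trains = {
        i + 1: slice_profile_echo_train(t2, spec_local.t1_of(t2), protocol)
        for i, t2 in enumerate(segment_t2)
    }
    stack, t2_truth, s0_truth = _render(label_map, trains, spec_local, protocol)

    model = SegmentModel(
        endo_contour=_circle(cx, cy, r_endo),
        epi_contour=_circle(cx, cy, r_epi),
        rv_insertion=np.array(
            [cx + (r_epi + 2.0) * np.cos(np.radians(phi_rv)),
             cy - (r_epi + 2.0) * np.sin(np.radians(phi_rv))]
        ),
        slice_level=slice_level,
    )
    aha_labels = np.where(label_map > 0, label_map + _LEVEL_OFFSET[slice_level], 0)
    truth = {
        "label_map": aha_labels,
        "t2_map": t2_truth,
        "s0_map": s0_truth,
        "segment_t2": dict(zip(segment_ids(slice_level), segment_t2)),
        "sigma": stack.noise.sigma,
    }
    return stack, model, truth
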