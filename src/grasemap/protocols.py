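"""GraSE sequence variants and their timing arithmetic.

A gradient-spin-echo (GraSE) multi-echo sequence generates a train of spin
echoes with refocusing pulses spaced ``delta_te`` apart; each spin echo is
read out with a short EPI echo train (``epi_factor`` phase-encode lines per
spin echo) and reconstructed into its own image at the effective echo time
of that spin echo.  Acquisition is ECG-triggered with one excitation per RR
interval, so the shot count directly sets the breath-hold duration.

The four protocol presets shipped with the package (``9Ec``, ``6Ec``,
``6EcLR`` and ``7Ec_no_se``) describe the clinically evaluated variants of
a breath-hold black-blood myocardial T2-mapping protocol at 1.5 T.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

import yaml

__all__ = [
    "GraSEProtocol",
    "preset",
    "preset_names",
    "echo_times",
    "shot_duration",
    "num_heartbeats",
    "breath_hold_duration",
    "black_blood_inversion_delay",
]

_VALID_PROFILES = ("ideal", "slr_optimized", "suboptimal")


@dataclass(frozen=True)
class GraSEProtocol:
    """Complete timing/geometry description of one GraSE sequence variant.

    Parameters
    ----------
    name:
        Human-readable label of the variant.
    first_te:
        Effective echo time of the first *reconstructed* echo image (ms).
    delta_te:
        Spacing between consecutive spin echoes (ms).
    n_echoes:
        Number of reconstructed echo images.
    n_startup:
        Number of start-up echoes acquired but discarded (0 or 1).  A
        start-up echo lets the echo train settle before imaging starts, so
        with one start-up echo ``first_te = 2 * delta_te``.
    epi_factor:
        Gradient echoes (k-space lines) acquired per spin echo.
    sense_factor:
        Parallel-imaging acceleration; divides the number of phase-encode
        lines that must actually be acquired.
    matrix_read, matrix_phase:
        Acquired matrix (frequency- and phase-encode samples).
    voxel_size:
        Acquired in-plane voxel size (mm, isotropic in-plane).
    slice_thickness:
        Slice thickness (mm).
    n_dummy:
        Dummy TRs (heartbeats) played before data acquisition.
    refocusing_profile:
        Label of the effective refocusing flip-angle profile across the
        slice: ``"ideal"``, ``"slr_optimized"`` or ``"suboptimal"``.
    """

    name: str
    first_te: float
    delta_te: float
    n_echoes: int
    n_startup: int = 1
    epi_factor: int = 7
    sense_factor: int = 2
    matrix_read: int = 176
    matrix_phase: int = 168
    voxel_size: float = 2.0
    slice_thickness: float = 10.0
    tr_mode: str = "one RR interval"
    n_dummy: int = 1
    refocusing_profile: str = "slr_optimized"

    def __post_init__(self) -> None:
        if self.n_echoes < 2:
            raise ValueError("a multi-echo protocol needs n_echoes >= 2")
        if self.delta_te <= 0:
            raise ValueError("delta_te must be positive")
        if self.n_startup not in (0, 1):
            raise ValueError("n_startup must be 0 or 1")
        if self.epi_factor < 1 or self.sense_factor < 1:
            raise ValueError("epi_factor and sense_factor must be >= 1")
        if self.refocusing_profile not in _VALID_PROFILES:
            raise ValueError(
                f"unknown refocusing_profile {self.refocusing_profile!r}; "
                f"valid: {_VALID_PROFILES}"
            )

    def with_profile(self, profile: str) -> "GraSEProtocol":
        """Copy of this protocol with a different refocusing profile."""
        return replace(self, refocusing_profile=profile)


def _load_presets() -> dict:
    text = resources.files("grasemap").joinpath("data/presets.yaml").read_text()
    return yaml.safe_load(text)


def preset_names() -> list[str]:
    """Names of the shipped protocol presets."""
    return list(_load_presets())


def preset(name: str) -> GraSEProtocol:
    """Return one of the shipped GraSE protocol presets.

    ``"6Ec"`` is the six-echo variant proposed for clinical use (first TE
    23.6 ms, echo spacing 11.8 ms, one start-up echo); ``"9Ec"`` acquires
    nine echoes; ``"6EcLR"`` trades resolution for SNR; ``"7Ec_no_se"``
    omits the start-up echo (first TE 11.8 ms).
    """
    presets = _load_presets()
    if name not in presets:
        raise KeyError(
            f"unknown protocol preset {name!r}; valid presets: {sorted(presets)}"
        )
    return GraSEProtocol(name=name, **presets[name])


def echo_times(p: GraSEProtocol) -> list[float]:
    """Effective echo times (ms) of the reconstructed echo images.

    Echoes are equally spaced: ``first_te + k * delta_te`` for
    ``k = 0 .. n_echoes - 1``.
    """
    return [p.first_te + k * p.delta_te for k in range(p.n_echoes)]


def shot_duration(p: GraSEProtocol) -> float:
    """Span of the refocusing train per excitation (ms).

    Counts every spin echo played out, including discarded start-up
    echoes: ``(n_echoes + n_startup) * delta_te``.
    """
    return (p.n_echoes + p.n_startup) * p.delta_te


def num_heartbeats(p: GraSEProtocol) -> int:
    """Heartbeats (RR intervals) needed for one slice, incl. dummy TRs.

    Each excitation acquires ``epi_factor`` phase-encode profiles per echo
    image and SENSE cuts the required lines by ``sense_factor``, so the
    number of imaging shots is ``ceil(matrix_phase / (sense * epi))``.
    """
    shots = math.ceil(p.matrix_phase / (p.sense_factor * p.epi_factor))
    return shots + p.n_dummy


def breath_hold_duration(p: GraSEProtocol, rr_interval: float) -> float:
    """Breath-hold duration in seconds for one slice at a given RR (ms)."""
    if rr_interval <= 0:
        raise ValueError("rr_interval must be positive")
    return num_heartbeats(p) * rr_interval / 1000.0


def black_blood_inversion_delay(rr_interval: float, t1_blood: float = 1200.0) -> float:
    """Inversion delay (ms) nulling flowing blood in a dual-IR module.

    With one non-selective inversion per RR interval the longitudinal
    magnetization of blood reaches a cyclic steady state; the delay at
    which it crosses zero is

        TI = T1 * ln( 2 / (1 + exp(-RR / T1)) )

    which tends to ``T1 * ln 2`` for long RR (single-shot limit).  The
    default blood T1 of 1200 ms is appropriate at 1.5 T.
    """
    if rr_interval <= 0:
        raise ValueError("rr_interval must be positive")
    if t1_blood <= 0:
        raise ValueError("t1_blood must be positive")
    return t1_blood * math.log(2.0 / (1.0 + math.exp(-rr_interval / t1_blood)))
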