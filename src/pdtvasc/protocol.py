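"""Acquisition protocol and arterial-input-function parameter containers.

All times are stored in seconds, concentrations in millimolar (mM) and
relaxivity in s^-1 mM^-1.  Ktrans is expressed in min^-1 at every public
surface (the field convention) and converted to s^-1 internally where a
formula mixes it with times in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence


@dataclass(frozen=True)
class ScanProtocol:
    """Constants of the MR acquisition shared by simulation and inversion.

    Defaults reproduce a 7T small-animal protocol: a variable-flip-angle
    (VFA) 3D FLASH T1 scan with 7 flip angles at TR = 20 ms, and a dynamic
    contrast-enhanced (DCE) FLASH scan at a fixed 7 deg flip angle,
    TR = 3 ms, one frame every 3.5 s for 15 min, with the contrast bolus
    injected 2 min after the start of the scan.  ``r1_relaxivity`` is the
    longitudinal relaxivity of the gadolinium agent (Dotarem,
    3.53 s^-1 mM^-1).
    """

    tr_vfa: float = 0.020
    te_vfa: float = 0.0032
    vfa_flip_angles: tuple[float, ...] = (2.0, 3.0, 5.0, 7.0, 10.0, 13.0, 20.0)
    tr_dce: float = 0.003
    te_dce: float = 0.001
    fa_dce: float = 7.0
    frame_interval: float = 3.5
    n_frames: int = 257          # 15 min / 3.5 s
    t0: float = 120.0            # injection time, s after scan start
    r1_relaxivity: float = 3.53  # s^-1 mM^-1

    def __post_init__(self) -> None:
        for name in ("tr_vfa", "te_vfa", "tr_dce", "te_dce", "frame_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        angles = tuple(float(a) for a in self.vfa_flip_angles)
        if any(not (0.0 < a < 90.0) for a in angles + (self.fa_dce,)):
            raise ValueError("flip angles must lie strictly between 0 and 90 degrees")
        object.__setattr__(self, "vfa_flip_angles", angles)
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not (0.0 <= self.t0 < self.n_frames * self.frame_interval):
            raise ValueError("injection time t0 must fall inside the scan window")
        if self.r1_relaxivity <= 0:
            raise ValueError("r1_relaxivity must be > 0")

    @property
    def frame_times(self):
        import numpy as np

        return np.arange(self.n_frames) * self.frame_interval

    def to_dict(self) -> dict:
        d = asdict(self)
        d["vfa_flip_angles"] = list(d["vfa_flip_angles"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScanProtocol":
        d = dict(d)
        d["vfa_flip_angles"] = tuple(d["vfa_flip_angles"])
        return cls(**d)


@dataclass(frozen=True)
class AifParams:
    """Bi-exponential population arterial input function.

    Cp(t) = A1 exp(-(t-t0)/tau1) + A2 exp(-(t-t0)/tau2) for t >= t0, else 0.
    Defaults are the published population values for a murine Dotarem bolus
    (amplitudes in mM, time constants in seconds).
    """

    a1: float = 5.36
    a2: float = 1.27
    tau1: float = 5.36
    tau2: float = 915.0

    def __post_init__(self) -> None:
        if self.a1 < 0 or self.a2 < 0:
            raise ValueError("AIF amplitudes must be >= 0")
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("AIF time constants must be > 0")
        if not self.tau1 < self.tau2:
            raise ValueError("tau1 must be smaller than tau2 (fast then slow decay)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AifParams":
        return cls(**d)


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model for the simulated signals.

    ``rician`` is the default for magnitude MR images; ``gaussian`` is kept
    for linear-regime checks.  ``sigma`` is the per-channel Gaussian width
    in signal units; the same ``seed`` always reproduces the same series.
    """

    model: str = "rician"
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("gaussian", "rician"):
            raise ValueError("noise model must be 'gaussian' or 'rician'")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseSpec":
        return cls(**d)
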