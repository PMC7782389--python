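"""Simulation configuration.

:class:`SetupConfig` collects every tunable of the synthetic EEG bench in
one flat structure whose field names follow the historical SETUP naming
convention of script-driven beamformer benchmarks, so configurations are
self-describing when serialized to JSON.

Conventions
-----------
* ``FRAC`` is the fraction of off-diagonal *ones* in the MVAR coefficient
  mask; the complementary zero-fraction (``frac_zero = 1 - FRAC``) is what
  the masking operation consumes.  The shipped default masks 80 % of the
  off-diagonal couplings.
* ``SRCS`` is a list of ROI rows ``[n_interest, n_interference,
  n_background]``; ``DEEP`` gives the same three counts for deep (central)
  sources.
* All signal-to-noise ratios (``SINR``, ``SBNR``, ``SMNR``) are electrode
  level power ratios in decibels.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

from .exceptions import ConfigError

__all__ = ["SetupConfig", "generate_default_config", "load_config", "save_config"]


_FLAG_FIELDS = (
    "ERPs",
    "H_Src_pert",
    "H_Int_pert",
    "WhtNoiseAddFlg",
    "SigPre",
    "IntPre",
    "BcgPre",
    "MesPre",
    "SigPst",
    "IntPst",
    "BcgPst",
    "MesPst",
)


@dataclass
class SetupConfig:
    # trial structure
    n00: int = 1000          # time samples per trial (split evenly pre/pst)
    K00: int = 20            # independent trial realizations
    SRATE: float = 256.0     # sampling rate [Hz], metadata only

    # source dynamics
    P00: int = 6             # MVAR order, sources of interest
    R00: int = 6             # MVAR order, background sources
    FRAC: float = 0.2        # fraction of off-diagonal ONES in the mask
    STAB: float = 0.95       # companion spectral-radius bound
    RNG: tuple = (-0.9, 0.9) # uniform range for coefficient draws
    ITER: int = 100          # retry budget for stable-model generation
    ERPs: int = 0            # add evoked (phase-locked) component to pst

    # geometry
    # One ROI row per patch: [interest, interference, background] counts.
    # Source types live in distinct patches; co-locating interest and
    # interference in one patch makes their lead-field columns nearly
    # parallel, which is both unrealistic and numerically degenerate.
    M00: int = 128                                    # electrode count
    SRCS: list = field(default_factory=lambda: [[3, 0, 0], [2, 0, 0],
                                                [0, 3, 0], [0, 2, 0],
                                                [0, 0, 5]])
    DEEP: list = field(default_factory=lambda: [0, 0, 0])
    CUBE: float = 0.010      # edge [m] of the location-perturbation cube
    CONE: float = math.pi / 32  # azimuth/elevation perturbation bound [rad]

    # noise calibration (electrode-level, dB)
    SINR: float = 5.0
    SBNR: float = 5.0
    SMNR: float = 5.0
    WhtNoiseAddFlg: int = 0
    WhtNoiseAddSNR: float = 10.0

    # which components enter the pre/pst mixtures
    SigPre: int = 0
    IntPre: int = 1
    BcgPre: int = 1
    MesPre: int = 1
    SigPst: int = 1
    IntPst: int = 1
    BcgPst: int = 1
    MesPst: int = 1

    # reconstruction
    H_Src_pert: int = 0      # reconstruct with perturbed interest lead-field
    H_Int_pert: int = 0      # null with perturbed interference lead-field
    RANK_EIG: int = 0        # eigenspace-projection rank; 0 = n active sources
    IntLfgRANK: int = 0      # interference lead-field rank; 0 = full

    # connectivity
    PDC_RES: int = 129       # points of the normalized-frequency grid [0, .5]

    # reproducibility
    SEED: int = 0

    # ------------------------------------------------------------------
    @property
    def frac_zero(self) -> float:
        """Fraction of off-diagonal mask entries forced to zero."""
        return 1.0 - self.FRAC

    @property
    def pre_len(self) -> int:
        return self.n00 // 2

    @property
    def pst_len(self) -> int:
        return self.n00 // 2

    def n_sources(self, column: int) -> int:
        """Total source count for column 0=interest, 1=interference, 2=background."""
        cortical = sum(int(row[column]) for row in self.SRCS)
        return cortical + int(self.DEEP[column])

    @property
    def n_interest(self) -> int:
        return self.n_sources(0)

    @property
    def n_interference(self) -> int:
        return self.n_sources(1)

    @property
    def n_background(self) -> int:
        return self.n_sources(2)

    # ------------------------------------------------------------------
    def validate(self) -> "SetupConfig":
        if self.n00 < 2 or self.n00 % 2 != 0:
            raise ConfigError(f"n00 must be a positive even integer, got {self.n00}")
        if self.K00 < 1:
            raise ConfigError(f"K00 must be >= 1, got {self.K00}")
        if not (0 < self.STAB <= 1):
            raise ConfigError(f"STAB must lie in (0, 1], got {self.STAB}")
        if not (0.0 <= self.FRAC <= 1.0):
            raise ConfigError(f"FRAC must lie in [0, 1], got {self.FRAC}")
        if self.ITER < 1:
            raise ConfigError("ITER must be a positive integer")
        if self.P00 < 1 or self.R00 < 1:
            raise ConfigError("MVAR orders P00 and R00 must be >= 1")
        for name in _FLAG_FIELDS:
            v = getattr(self, name)
            if v not in (0, 1):
                raise ConfigError(f"flag {name} must be 0 or 1, got {v!r}")
        for name in ("SINR", "SBNR", "SMNR"):
            if not math.isfinite(getattr(self, name)):
                raise ConfigError(f"{name} must be finite")
        if len(self.DEEP) != 3 or any(int(d) < 0 for d in self.DEEP):
            raise ConfigError("DEEP must be three nonnegative integers")
        for row in self.SRCS:
            if len(row) != 3 or any(int(c) < 0 for c in row):
                raise ConfigError("each SRCS row must be three nonnegative integers")
        if self.n_interest < 1:
            raise ConfigError("at least one source of interest is required")
        if self.M00 < 4:
            raise ConfigError("M00 (electrode count) must be >= 4")
        if self.CUBE < 0:
            raise ConfigError("CUBE must be >= 0")
        if not (0 <= self.CONE < math.pi / 2):
            raise ConfigError("CONE must lie in [0, pi/2)")
        if self.PDC_RES < 2:
            raise ConfigError("PDC_RES must be >= 2")
        lo, hi = self.RNG
        if not lo < hi:
            raise ConfigError("RNG must be an increasing (low, high) interval")
        return self

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["RNG"] = list(self.RNG)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SetupConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration fields: {sorted(unknown)}")
        d = dict(d)
        if "RNG" in d:
            d["RNG"] = tuple(d["RNG"])
        return cls(**d).validate()


def generate_default_config() -> SetupConfig:
    """Default bench configuration: order-6 masked MVAR sources (80 % of
    off-diagonal couplings zeroed), 128 electrodes, 5 interest / 5
    interference / 5 background cortical sources, 10 mm / pi/32 lead-field
    perturbations."""
    return SetupConfig().validate()


def load_config(path: str | Path) -> SetupConfig:
    with open(path) as fh:
        return SetupConfig.from_dict(json.load(fh))


def save_config(config: SetupConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(config.to_dict(), fh, indent=2)
        fh.write("\n")
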