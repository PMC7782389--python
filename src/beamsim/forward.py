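"""Sensor-space signal assembly.

Source activity is propagated to the electrodes through the lead-field
matrices, each noise component is rescaled so that the electrode-level
power ratios (signal/interference, signal/background, signal/measurement,
all in dB) match the configured targets exactly, and the components are
summed — per the pre/pst component flags — into the trial recording

    y = H q + H_i q_i + H_b q_b + n_m.

Power is pooled over channels, samples and trials of the *pst* interval
(the interval where the signal of interest lives), so a given realization
achieves the configured decibel ratios exactly, not just in expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .config import SetupConfig
from .exceptions import DegenerateInputError, InvalidArgumentError
from .head import Leadfield
from .mvar import SourceModels, SourceTimecourses, assemble_sources, generate_source_models
from .rng import RandomStreams

__all__ = [
    "TrialData",
    "project_to_sensors",
    "adjust_snr",
    "build_recording",
    "simulate_recording",
    "save_recording",
]

COMPONENTS = ("signal", "interference", "background", "measurement")


@dataclass
class TrialData:
    """Trials x channels x samples sensor recording with pre/pst split.

    ``components`` retains the per-type breakdown (same shape as ``data``)
    so that ``data`` equals the flag-gated sum of its parts exactly.
    """

    data: np.ndarray
    pre_len: int
    pst_len: int
    components: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise InvalidArgumentError("data must be trials x channels x samples")
        if self.data.shape[2] != self.pre_len + self.pst_len:
            raise InvalidArgumentError("sample count != pre_len + pst_len")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def y_pre(self) -> np.ndarray:
        return self.data[:, :, : self.pre_len]

    @property
    def y_pst(self) -> np.ndarray:
        return self.data[:, :, self.pre_len :]


def _gain(H) -> np.ndarray:
    return H.gain if isinstance(H, Leadfield) else np.asarray(H, dtype=float)


def project_to_sensors(
    signals: SourceTimecourses,
    H,
    H_i,
    H_b,
) -> Dict[str, np.ndarray]:
    """Propagate each source component to the sensors (no mixing yet).

    Returns channel x sample arrays keyed by component name.
    """
    out = {}
    for name, gain, src in (
        ("signal", _gain(H), signals.q),
        ("interference", _gain(H_i), signals.q_i),
        ("background", _gain(H_b), signals.q_b),
    ):
        if src.shape[0] == 0:
            out[name] = np.zeros((gain.shape[0], signals.pre_len + signals.pst_len))
            continue
        if gain.shape[1] != src.shape[0]:
            raise InvalidArgumentError(
                f"{name}: lead-field has {gain.shape[1]} columns "
                f"but {src.shape[0]} sources were simulated"
            )
        out[name] = gain @ src
    return out


def power(x: np.ndarray) -> float:
    """Mean squared entry over all axes."""
    x = np.asarray(x)
    if x.size == 0:
        return 0.0
    return float(np.mean(x**2))


def adjust_snr(reference: np.ndarray, component: np.ndarray, target_db: float) -> np.ndarray:
    """Scale ``component`` so 10 log10(P(reference)/P(scaled)) == target_db.

    P is the mean squared entry pooled over all channels/samples/trials.
    """
    p_ref = power(reference)
    p_comp = power(component)
    if p_comp == 0.0:
        raise DegenerateInputError("component has zero power; SNR scaling undefined")
    scale = np.sqrt(p_ref / (p_comp * 10.0 ** (target_db / 10.0)))
    return component * scale


def _calibrate_pst(sig_pst: np.ndarray, component: np.ndarray, pre: int,
                   target_db: float) -> np.ndarray:
    """Scale the whole component so its *pst* power meets ``target_db``.

    The SNR targets are defined on the interval where the signal of
    interest lives, so the scale factor is computed from the pst slices
    only, then applied to both halves (the pre half keeps the component's
    natural pre/pst power ratio).
    """
    p_ref = power(sig_pst)
    p_comp = power(component[:, :, pre:])
    if p_comp == 0.0:
        raise DegenerateInputError("component has zero pst power; SNR scaling undefined")
    scale = np.sqrt(p_ref / (p_comp * 10.0 ** (target_db / 10.0)))
    return component * scale


def build_recording(
    config: SetupConfig,
    components: Dict[str, np.ndarray],
    rng: np.random.Generator,
) -> TrialData:
    """Mix the calibrated sensor components into the trial recording.

    ``components`` maps 'signal'/'interference'/'background' to trials x
    channels x samples arrays (already SINR/SBNR-calibrated).  White
    Gaussian measurement noise is generated here and calibrated to SMNR
    against the pst interval of the signal component; the pre and pst
    halves are then flag-gated sums of their active components.
    """
    pre, pst = config.pre_len, config.pst_len
    shapes = {c.shape for c in components.values()}
    if len(shapes) != 1:
        raise InvalidArgumentError("all components must share one shape")
    shape = shapes.pop()
    if shape[2] != pre + pst:
        raise InvalidArgumentError("component samples != n00")

    if not (config.SigPst or config.IntPst or config.BcgPst or config.MesPst):
        warnings.warn(
            "all pst component flags are zero: the recording carries no "
            "post-onset activity and reconstruction is impossible",
            stacklevel=2,
        )

    noise = rng.standard_normal(shape)
    sig_pst = components["signal"][:, :, pre:]
    if power(sig_pst) > 0:
        noise = _calibrate_pst(sig_pst, noise, pre, config.SMNR)

    comps = dict(components)
    comps["measurement"] = noise

    flags_pre = {
        "signal": config.SigPre,
        "interference": config.IntPre,
        "background": config.BcgPre,
        "measurement": config.MesPre,
    }
    flags_pst = {
        "signal": config.SigPst,
        "interference": config.IntPst,
        "background": config.BcgPst,
        "measurement": config.MesPst,
    }
    data = np.zeros(shape)
    for name in COMPONENTS:
        if flags_pre[name]:
            data[:, :, :pre] += comps[name][:, :, :pre]
        if flags_pst[name]:
            data[:, :, pre:] += comps[name][:, :, pre:]

    return TrialData(data=data, pre_len=pre, pst_len=pst, components=comps)


def simulate_recording(
    config: SetupConfig,
    streams: RandomStreams,
    H,
    H_i,
    H_b,
    models: Optional[SourceModels] = None,
) -> tuple:
    """Simulate the full K00-trial recording.

    Returns ``(recording, sources)`` where ``sources`` is the list of
    per-trial :class:`SourceTimecourses` (needed later as ground truth).
    Interference and background components are calibrated to SINR/SBNR
    against the signal component, pooling power over the pst interval of
    all trials.
    """
    config.validate()
    if models is None:
        models = generate_source_models(config, streams)

    trials: List[SourceTimecourses] = []
    stacked = {name: [] for name in ("signal", "interference", "background")}
    for k in range(config.K00):
        src = assemble_sources(config, streams, models=models, trial=k)
        trials.append(src)
        comp = project_to_sensors(src, H, H_i, H_b)
        for name in stacked:
            stacked[name].append(comp[name])
    arrays = {name: np.stack(v) for name, v in stacked.items()}

    pre = config.pre_len
    sig_pst = arrays["signal"][:, :, pre:]
    if power(arrays["interference"]) > 0:
        arrays["interference"] = _calibrate_pst(
            sig_pst, arrays["interference"], pre, config.SINR
        )
    if power(arrays["background"]) > 0:
        if config.WhtNoiseAddFlg:
            # optional white admixture inside the background component,
            # scaled against background power before SBNR calibration
            wn = streams.get("noise:background-white").standard_normal(
                arrays["background"].shape
            )
            arrays["background"] = arrays["background"] + adjust_snr(
                arrays["background"], wn, config.WhtNoiseAddSNR
            )
        arrays["background"] = _calibrate_pst(
            sig_pst, arrays["background"], pre, config.SBNR
        )

    recording = build_recording(config, arrays, streams.get("noise:measurement"))
    return recording, trials


def save_recording(recording: TrialData, path) -> None:
    """Binary array archive (.npz) plus channel-count metadata inside."""
    np.savez_compressed(
        path,
        data=recording.data,
        pre_len=recording.pre_len,
        pst_len=recording.pst_len,
        **{f"component_{k}": v for k, v in recording.components.items()},
    )
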