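"""Forward simulation of multiecho gradient-echo magnitude signals.

A voxel containing water and fat produces a transverse signal that decays
with an effective relaxation time T2* while the fat resonances, shifted in
frequency from water, beat against the water signal and superimpose an
oscillation on the exponential decay.  The magnitude signal at echo time
``TE`` (ms) is modeled as

    S(TE) = S0 * | (1 - FF) + FF * sum_p a_p * exp(2*pi*i*f_p*TE) | * exp(-TE/T2*)

with a single T2* shared by water and fat, fat fraction ``FF`` in [0, 1],
and a multipeak fat spectrum of frequency offsets ``f_p`` (Hz, relative to
water) with relative amplitudes ``a_p`` summing to one.  Magnitude images
carry Rician noise, which produces a positive signal floor at low SNR.

This module is purely forward: it evaluates the model and corrupts it with
noise.  The inverse problem lives in :mod:`ferrofat.relaxometry`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GAMMA_BAR_MHZ_PER_T",
    "FatSpectrum",
    "AcquisitionProtocol",
    "TissueState",
    "EchoTrain",
    "evaluate_signal",
    "add_magnitude_noise",
]

#: Proton gyromagnetic ratio over 2*pi, MHz/T.  1 ppm at field B0 (T) is
#: GAMMA_BAR_MHZ_PER_T * B0 Hz.
GAMMA_BAR_MHZ_PER_T = 42.5774785


class ProtocolError(ValueError):
    """Invalid acquisition protocol (e.g. empty or non-increasing echo list)."""


@dataclass(frozen=True)
class FatSpectrum:
    """Multipeak fat spectrum: frequency offsets from water with amplitudes.

    Parameters
    ----------
    peaks
        Tuple of ``(offset_hz, relative_amplitude)`` pairs.  Offsets are in
        Hz relative to the water resonance at ``field_strength_t``;
        amplitudes are non-negative and must sum to 1 within 1e-9.
    field_strength_t
        Static field strength in tesla (default 1.5 T, the clinical
        standard for iron quantification).
    """

    peaks: tuple[tuple[float, float], ...]
    field_strength_t: float = 1.5

    def __post_init__(self) -> None:
        if len(self.peaks) < 1:
            raise ValueError("FatSpectrum requires at least one peak")
        offs = np.array([p[0] for p in self.peaks], dtype=float)
        amps = np.array([p[1] for p in self.peaks], dtype=float)
        if not np.all(np.isfinite(offs)):
            raise ValueError("peak frequency offsets must be finite")
        if np.any(amps < 0):
            raise ValueError("peak amplitudes must be non-negative")
        if abs(amps.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"relative amplitudes must sum to 1 (got {amps.sum()!r})"
            )
        if self.field_strength_t <= 0:
            raise ValueError("field strength must be positive")

    @property
    def offsets_hz(self) -> np.ndarray:
        return np.array([p[0] for p in self.peaks], dtype=float)

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([p[1] for p in self.peaks], dtype=float)

    @classmethod
    def from_ppm(
        cls,
        ppm_offsets,
        relative_amplitudes,
        field_strength_t: float = 1.5,
    ) -> "FatSpectrum":
        """Build a spectrum from chemical-shift offsets in ppm.

        Offsets are relative to water (positive = downfield of water);
        amplitudes are normalized to sum to one.
        """
        ppm = np.asarray(ppm_offsets, dtype=float)
        amps = np.asarray(relative_amplitudes, dtype=float)
        if ppm.shape != amps.shape:
            raise ValueError("ppm offsets and amplitudes must have equal length")
        total = amps.sum()
        if total <= 0:
            raise ValueError("amplitudes must have positive sum")
        hz = ppm * GAMMA_BAR_MHZ_PER_T * field_strength_t
        amps = amps / total
        return cls(
            peaks=tuple(zip(hz.tolist(), amps.tolist())),
            field_strength_t=field_strength_t,
        )

    def phasor(self, echo_times_ms) -> np.ndarray:
        """Complex fat phasor ``sum_p a_p exp(2 pi i f_p TE)`` at each TE (ms)."""
        te_s = np.asarray(echo_times_ms, dtype=float) * 1e-3
        return np.exp(2j * np.pi * np.outer(te_s, self.offsets_hz)) @ self.amplitudes


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Echo-time grid of a multiecho gradient-echo acquisition."""

    echo_times_ms: tuple[float, ...]
    organ: str = "pancreas"

    def __post_init__(self) -> None:
        te = np.asarray(self.echo_times_ms, dtype=float)
        if te.size == 0:
            raise ProtocolError("echo list is empty")
        if te.size < 4:
            raise ProtocolError("protocol requires at least 4 echo times")
        if np.any(te <= 0):
            raise ProtocolError("echo times must be positive")
        if np.any(np.diff(te) <= 0):
            raise ProtocolError("echo times must be strictly increasing")
        if self.organ not in ("pancreas", "liver", "heart"):
            raise ProtocolError(f"unknown organ label: {self.organ!r}")

    @classmethod
    def uniform(
        cls, first_te_ms: float, delta_te_ms: float, n_echoes: int, organ: str = "pancreas"
    ) -> "AcquisitionProtocol":
        te = first_te_ms + delta_te_ms * np.arange(n_echoes)
        return cls(echo_times_ms=tuple(te.tolist()), organ=organ)


@dataclass(frozen=True)
class TissueState:
    """Ground-truth tissue parameters for one ROI."""

    s0: float
    t2star_ms: float
    ff: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.s0 <= 0:
            raise ValueError("S0 must be positive")
        if self.t2star_ms <= 0:
            raise ValueError("T2* must be positive")
        if not 0.0 <= self.ff <= 1.0:
            raise ValueError("FF must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")


@dataclass(frozen=True)
class EchoTrain:
    """One ROI's decay curve: echo times (ms) and mean magnitude signals."""

    echo_times_ms: np.ndarray
    signals: np.ndarray
    organ: str | None = None
    region: str | None = None

    def __post_init__(self) -> None:
        te = np.asarray(self.echo_times_ms, dtype=float)
        s = np.asarray(self.signals, dtype=float)
        if te.shape != s.shape or te.ndim != 1:
            raise ValueError("echo times and signals must be 1-D arrays of equal length")
        if np.any(s < 0):
            raise ValueError("magnitude signals must be non-negative")
        object.__setattr__(self, "echo_times_ms", te)
        object.__setattr__(self, "signals", s)

    def __len__(self) -> int:
        return self.echo_times_ms.size

    def truncated(self, n_echoes: int) -> "EchoTrain":
        """First ``n_echoes`` echoes as a new train."""
        return replace(
            self,
            echo_times_ms=self.echo_times_ms[:n_echoes],
            signals=self.signals[:n_echoes],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"te_ms": self.echo_times_ms, "signal": self.signals})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, organ: str | None = None, region: str | None = None) -> "EchoTrain":
        df = pd.read_csv(path)
        missing = {"te_ms", "signal"} - set(df.columns)
        if missing:
            raise ValueError(f"echo-train file missing columns: {sorted(missing)}")
        return cls(
            echo_times_ms=df["te_ms"].to_numpy(float),
            signals=df["signal"].to_numpy(float),
            organ=organ,
            region=region,
        )


def evaluate_signal(
    state: TissueState, protocol: AcquisitionProtocol, spectrum: FatSpectrum
) -> EchoTrain:
    """Noiseless forward evaluation of the fat-water magnitude model.

    ``FF = 0`` reduces to a monoexponential decay and the TE -> 0 limit is
    ``S0``.  The noise SD carried by ``state`` is ignored here; use
    :func:`add_magnitude_noise` to corrupt the result.
    """
    te = np.asarray(protocol.echo_times_ms, dtype=float)
    modulation = np.abs((1.0 - state.ff) + state.ff * spectrum.phasor(te))
    signals = state.s0 * np.exp(-te / state.t2star_ms) * modulation
    return EchoTrain(echo_times_ms=te, signals=signals, organ=protocol.organ)


def add_magnitude_noise(
    train: EchoTrain,
    noise_sd: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> EchoTrain:
    """Corrupt a train with Rician noise.

    Each noisy signal is ``|(s + n_re) + i*n_im|`` with independent
    Gaussian(0, noise_sd) components — the magnitude-MRI noise model,
    whose zero-signal mean is ``noise_sd * sqrt(pi/2)`` (Rayleigh).
    """
    if noise_sd < 0:
        raise ValueError("noise SD must be non-negative")
    if noise_sd == 0:
        return train
    if rng is None:
        rng = np.random.default_rng(seed)
    re = rng.normal(0.0, noise_sd, size=train.signals.shape)
    im = rng.normal(0.0, noise_sd, size=train.signals.shape)
    return replace(train, signals=np.hypot(train.signals + re, im))
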