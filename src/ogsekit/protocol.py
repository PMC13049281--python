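"""The acquisition protocol: an ordered collection of encoding spectra.

The study protocol spans two frequency-varying regimes: fixed total waveform
time T (30 Hz-N1, 65 Hz-N2, 90 Hz-N3, all near T = 80 ms) and fixed
oscillation count N = 1 (30, 40, 50, 60 Hz).  30 Hz-N1 belongs to both.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .waveforms import (
    EncodingSpectrum,
    WaveformSpec,
    build_waveform,
    compute_spectrum,
    solve_amplitude_for_b,
)

__all__ = ["Protocol", "build_protocol", "STUDY_PROTOCOL_ROWS", "study_protocol"]

#: (label, input frequency Hz, N, mixing time ms) of the six study waveforms.
#: Mixing times are the peak-to-side-lobe optimized values, except 30 Hz-N1
#: whose optimum is impractically long and which uses the scanner minimum.
STUDY_PROTOCOL_ROWS: tuple[tuple[str, float, int, float], ...] = (
    ("90Hz-N3", 90.0, 3, 10.1),
    ("65Hz-N2", 65.0, 2, 15.2),
    ("30Hz-N1", 30.0, 1, 7.4),
    ("40Hz-N1", 40.0, 1, 30.9),
    ("50Hz-N1", 50.0, 1, 24.7),
    ("60Hz-N1", 60.0, 1, 20.4),
)

#: Labels of the fixed-T and fixed-N series within the study protocol.
FIXED_T_LABELS = ("30Hz-N1", "65Hz-N2", "90Hz-N3")
FIXED_N_LABELS = ("30Hz-N1", "40Hz-N1", "50Hz-N1", "60Hz-N1")


@dataclass(frozen=True)
class Protocol:
    """Ordered collection of encoding spectra sharing one target b-value."""

    spectra: tuple[EncodingSpectrum, ...]
    b_target: float

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def __getitem__(self, key: int | str) -> EncodingSpectrum:
        if isinstance(key, str):
            for s in self.spectra:
                if s.label == key:
                    return s
            raise KeyError(key)
        return self.spectra[key]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.spectra)

    def subset(self, labels: Sequence[str]) -> "Protocol":
        return Protocol(spectra=tuple(self[lab] for lab in labels), b_target=self.b_target)

    def derived_table(self) -> pd.DataFrame:
        """Input and derived waveform parameters, one row per waveform."""
        rows = []
        for s in self.spectra:
            spec = s.waveform.spec
            rows.append(
                {
                    "label": s.label,
                    "input_frequency_hz": spec.input_frequency,
                    "n_oscillations": spec.n_oscillations,
                    "mixing_time_ms": spec.mixing_time,
                    "total_time_ms": s.waveform.total_duration,
                    "peak_frequency_hz": s.peak_frequency,
                    "gradient_mT_per_m": spec.gradient_amplitude,
                    "b_ms_per_um2": s.b_value,
                    "v_omega_sqrt_per_ms": s.v_omega,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        cols = [
            "label",
            "input_frequency_hz",
            "n_oscillations",
            "mixing_time_ms",
            "gradient_mT_per_m",
            "b_ms_per_um2",
        ]
        self.derived_table()[cols].to_csv(path, index=False)


def build_protocol(
    table: Iterable[tuple[str, float, int, float]] | pd.DataFrame = STUDY_PROTOCOL_ROWS,
    b_target: float = 2.0,
    ramp_time: float = 1.6,
    raster: float = 0.01,
    max_gradient: float = 500.0,
) -> Protocol:
    """Build all waveforms of a protocol with amplitudes solved for one b-value.

    Parameters
    ----------
    table : iterable of (label, input_frequency_hz, n_oscillations, mixing_time_ms)
        or a DataFrame with those columns.
    b_target : float
        Shared diffusion weighting in ms/um^2.
    """
    if isinstance(table, pd.DataFrame):
        rows = [
            (
                str(r.get("label", f"{r['input_frequency_hz']:g}Hz-N{int(r['n_oscillations'])}")),
                float(r["input_frequency_hz"]),
                int(r["n_oscillations"]),
                float(r["mixing_time_ms"]),
            )
            for _, r in table.iterrows()
        ]
    else:
        rows = [(str(a), float(b), int(c), float(d)) for a, b, c, d in table]
    spectra = []
    for label, f0, n, tm in rows:
        base = WaveformSpec(
            input_frequency=f0,
            n_oscillations=n,
            mixing_time=tm,
            ramp_time=ramp_time,
            raster=raster,
            max_gradient=max_gradient,
            label=label,
        )
        g = solve_amplitude_for_b(base, b_target)
        spec = WaveformSpec(
            input_frequency=f0,
            n_oscillations=n,
            mixing_time=tm,
            ramp_time=ramp_time,
            gradient_amplitude=g,
            raster=raster,
            max_gradient=max_gradient,
            label=label,
        )
        spectra.append(compute_spectrum(build_waveform(spec)))
    return Protocol(spectra=tuple(spectra), b_target=b_target)


def study_protocol(b_target: float = 2.0, raster: float = 0.01) -> Protocol:
    """The six-waveform study protocol with optimized mixing times."""
    return build_protocol(STUDY_PROTOCOL_ROWS, b_target=b_target, raster=raster)
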