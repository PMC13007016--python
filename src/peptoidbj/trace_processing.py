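"""Normalization of break-junction pulling traces.

A pulling trace records conductance versus electrode displacement during
junction elongation. Conductance is expressed as log10(G/G0) with
G0 = 2e²/h = 77.48 μS the conductance quantum. Traces are aligned so that
displacement zero sits at the final downward crossing of 0.5 G0 — the
point where the metallic contact has just broken — and analysis windows
(default log(G/G0) in [-5.5, 0], displacement in [-0.1, 1.0] nm) are
applied downstream by the histogram and featurization stages.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = [
    "G0_SIEMENS",
    "Trace",
    "AlignmentSpec",
    "AlignmentError",
    "to_log_conductance",
    "align_trace",
    "align_ensemble",
]

G0_SIEMENS = 77.48e-6  # conductance quantum, 2e^2/h


@dataclass
class Trace:
    """One pulling event: paired displacement (nm) and log10(G/G0) series.

    ``truth`` optionally carries generator ground-truth labels
    (``has_molecule``, ``population``, ``plateau_log_g``...) so downstream
    stages can be validated against known inputs.
    """

    trace_id: str
    displacement_nm: np.ndarray
    log_g: np.ndarray
    bias_mV: float = 250.0
    truth: Optional[dict] = None

    def __post_init__(self) -> None:
        self.displacement_nm = np.asarray(self.displacement_nm, dtype=float)
        self.log_g = np.asarray(self.log_g, dtype=float)
        if self.displacement_nm.shape != self.log_g.shape:
            raise ValueError("displacement and log_g series must have equal length")
        if self.displacement_nm.ndim != 1:
            raise ValueError("series must be one-dimensional")

    def __len__(self) -> int:
        return len(self.log_g)


@dataclass
class AlignmentSpec:
    """Alignment threshold and analysis windows.

    ``align_level_g0`` is in G0 units; the windows are closed intervals in
    log10(G/G0) and nm respectively.
    """

    align_level_g0: float = 0.5
    clip_log_g: tuple[float, float] = (-5.5, 0.0)
    clip_displacement_nm: tuple[float, float] = (-0.1, 1.0)

    def __post_init__(self) -> None:
        if not (0.0 < self.align_level_g0 <= 1.0):
            raise ValueError("align level must be in (0, 1] G0")
        if self.clip_log_g[0] >= self.clip_log_g[1]:
            raise ValueError("empty conductance window")
        if self.clip_displacement_nm[0] >= self.clip_displacement_nm[1]:
            raise ValueError("empty displacement window")


class AlignmentError(ValueError):
    """Raised when a trace never crosses the alignment level."""


def to_log_conductance(current_A, bias_mV: float,
                       noise_floor_log_g: float = -6.5):
    """Convert a current series (A) at a given bias to log10(G/G0).

    Values below the detection floor (including zero and negative currents)
    are clamped to ``noise_floor_log_g``. Non-finite samples are flagged.

    Returns ``(log_g, rejected)`` where ``rejected`` is a boolean mask of
    non-finite input samples (their output is set to the floor).
    """
    if bias_mV <= 0:
        raise ValueError("bias must be positive")
    current = np.asarray(current_A, dtype=float)
    rejected = ~np.isfinite(current)
    g_rel = np.where(rejected, 0.0, current) / (bias_mV * 1e-3) / G0_SIEMENS
    with np.errstate(divide="ignore", invalid="ignore"):
        log_g = np.log10(np.maximum(g_rel, 0.0))
    log_g = np.where(np.isfinite(log_g), log_g, -np.inf)
    log_g = np.maximum(log_g, noise_floor_log_g)
    return log_g, rejected


def _last_downward_crossing(displacement: np.ndarray, log_g: np.ndarray,
                            level: float) -> float:
    """Displacement of the last downward crossing of ``level`` (log10 units),
    linearly interpolated; ties broken toward larger displacement."""
    above = log_g >= level
    crossing = None
    for i in range(len(log_g) - 1):
        if above[i] and not above[i + 1]:
            y0, y1 = log_g[i], log_g[i + 1]
            d0, d1 = displacement[i], displacement[i + 1]
            if y0 == y1:  # degenerate: treat the later sample as the crossing
                crossing = d1
            else:
                crossing = d0 + (level - y0) * (d1 - d0) / (y1 - y0)
    if crossing is None:
        raise AlignmentError("trace never crosses the alignment level downward")
    return float(crossing)


def align_trace(trace: Trace, spec: AlignmentSpec | None = None) -> Trace:
    """Shift displacements so the final downward crossing of the alignment
    level maps to 0 nm.

    The full series is retained (windowing happens at histogramming); the
    operation is a pure translation of the displacement axis and is
    idempotent.
    """
    spec = spec or AlignmentSpec()
    level = float(np.log10(spec.align_level_g0))
    d0 = _last_downward_crossing(trace.displacement_nm, trace.log_g, level)
    return replace(trace, displacement_nm=trace.displacement_nm - d0)


def align_ensemble(traces, spec: AlignmentSpec | None = None):
    """Align every trace; traces that never cross the level are excluded.

    Returns ``(aligned, report)`` where ``report`` lists excluded trace ids
    with reasons and the excluded fraction — exclusions are never silent.
    """
    spec = spec or AlignmentSpec()
    aligned = []
    excluded = []
    for tr in traces:
        try:
            aligned.append(align_trace(tr, spec))
        except AlignmentError as exc:
            excluded.append({"trace_id": tr.trace_id, "reason": str(exc)})
    report = {
        "n_input": len(traces),
        "n_aligned": len(aligned),
        "excluded": excluded,
        "excluded_fraction": len(excluded) / len(traces) if traces else 0.0,
    }
    return aligned, report
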