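"""Parameter containers for the two-boundary Wiener diffusion model.

The model describes a two-choice lexical decision as noisy accumulation of
evidence between a lower ("nonword") and an upper ("word") absorbing
boundary.  One :class:`DiffusionParams` instance describes one experimental
condition; across-trial variability in drift, starting point and
non-decision time, plus a small contaminant mixture, are part of the
condition's parameter set.

All evidence-scale parameters (``v``, ``a``, ``sz``, ``eta``) are expressed
under the classic within-trial diffusion coefficient convention ``s = 0.1``.
Times are in seconds internally; trial tables use milliseconds.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace, asdict
from typing import Mapping


class ResponseSide(enum.Enum):
    """The two absorbing boundaries and their fixed response mapping."""

    UPPER = "word"
    LOWER = "nonword"

    @property
    def label(self) -> str:
        return self.value

    @property
    def opposite(self) -> "ResponseSide":
        return ResponseSide.LOWER if self is ResponseSide.UPPER else ResponseSide.UPPER


#: Side holding the correct response for each lexicality.
CORRECT_SIDE: Mapping[str, ResponseSide] = {
    "word": ResponseSide.UPPER,
    "nonword": ResponseSide.LOWER,
}

#: RT window (seconds) of the analysis stage; also the support of the
#: contaminant RT distribution.
CONTAMINANT_WINDOW = (0.25, 1.5)


class ParameterError(ValueError):
    """Raised when a diffusion parameter set violates its domain."""


@dataclass(frozen=True)
class DiffusionParams:
    """Nine-parameter diffusion model for one condition.

    Parameters
    ----------
    v : float
        Mean drift rate (evidence units / s).  Positive drifts push toward
        the upper ("word") boundary; word conditions are positive, nonword
        conditions negative.
    a : float
        Boundary separation (evidence units); response caution.
    zr : float
        Relative starting point in (0, 1); absolute start is ``z = zr * a``.
    t_er : float
        Mean non-decision time (s): stimulus encoding plus motor execution.
    eta : float
        SD of the normal across-trial drift distribution.
    sz : float
        Range of the uniform across-trial distribution of the *absolute*
        starting point (evidence units).
    st : float
        Range of the uniform across-trial distribution of non-decision time
        (s).
    p0 : float
        Contaminant proportion: trials whose RT is uniform on the analysis
        window rather than generated by the diffusion process.
    s : float
        Within-trial diffusion coefficient (scaling constant), 0.1 by
        convention.
    """

    v: float
    a: float
    zr: float
    t_er: float
    eta: float = 0.0
    sz: float = 0.0
    st: float = 0.0
    p0: float = 0.0
    s: float = 0.1

    def __post_init__(self) -> None:
        vals = asdict(self)
        for name, val in vals.items():
            if not math.isfinite(val):
                raise ParameterError(f"{name} must be finite, got {val!r}")
        if self.a <= 0:
            raise ParameterError(f"boundary separation a must be > 0, got {self.a}")
        if not 0.0 < self.zr < 1.0:
            raise ParameterError(f"relative start zr must be in (0, 1), got {self.zr}")
        if self.s <= 0:
            raise ParameterError(f"diffusion coefficient s must be > 0, got {self.s}")
        for name in ("eta", "sz", "st"):
            if vals[name] < 0:
                raise ParameterError(f"{name} must be >= 0, got {vals[name]}")
        if not 0.0 <= self.p0 < 1.0:
            raise ParameterError(f"contaminant proportion p0 must be in [0, 1), got {self.p0}")
        z = self.zr * self.a
        if z - self.sz / 2 <= 0 or z + self.sz / 2 >= self.a:
            raise ParameterError(
                "starting-point variability leaves the boundary interval: "
                f"z={z:.4g}, sz={self.sz:.4g}, a={self.a:.4g}"
            )
        if self.t_er - self.st / 2 < 0:
            raise ParameterError(
                f"non-decision variability goes negative: t_er={self.t_er}, st={self.st}"
            )

    @property
    def z(self) -> float:
        """Absolute starting point ``zr * a``."""
        return self.zr * self.a

    def without_variability(self) -> "DiffusionParams":
        """Single-trial kernel: variabilities and contaminants stripped."""
        return replace(self, eta=0.0, sz=0.0, st=0.0, p0=0.0)

    def replace(self, **kwargs) -> "DiffusionParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "DiffusionParams":
        return cls(**{k: float(v) for k, v in d.items()})


#: Condition key: (lexicality, repetition).
Condition = tuple[str, str]

CONDITIONS: tuple[Condition, ...] = (
    ("word", "nonrepeated"),
    ("word", "repeated"),
    ("nonword", "nonrepeated"),
    ("nonword", "repeated"),
)

# Group-level parameter estimates for the four repetition x lexicality
# conditions of a two-block lexical decision experiment (24 subjects,
# 200 block-2 trials each).  Boundary, start ratio, variabilities and the
# contaminant rate are shared across conditions; drift and non-decision
# time differ by condition.  These serve both as generative truth for the
# synthetic-data module and as the default fixed values of the constrained
# fitter.
_SHARED = dict(a=0.10, zr=0.54, eta=0.034, sz=0.002, st=0.14, p0=0.005, s=0.1)

REFERENCE_PARAMS: Mapping[Condition, DiffusionParams] = {
    ("word", "nonrepeated"): DiffusionParams(v=0.32, t_er=0.406, **_SHARED),
    ("word", "repeated"): DiffusionParams(v=0.36, t_er=0.400, **_SHARED),
    ("nonword", "nonrepeated"): DiffusionParams(v=-0.37, t_er=0.445, **_SHARED),
    ("nonword", "repeated"): DiffusionParams(v=-0.31, t_er=0.439, **_SHARED),
}
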