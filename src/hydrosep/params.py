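"""Window-based hydrophobicity parameters and per-peptide extrema.

Five parameters are computed in every length-10 sliding window of a peptide
(all normalised by the window length L so values are comparable):

* average hydrophobicity:  (1/L) sum h_i
* hydrophobic moment at angle delta (100 deg for helices, 180 deg for
  strands):  (1/L) sqrt[(sum h_i sin(i d))^2 + (sum h_i cos(i d))^2]
* alternating hydrophobicity:  (1/L) |sum (-1)^i h_i|  — identical to the
  180-degree moment by the analytic identity sin(i pi) = 0,
  cos(i pi) = (-1)^i; it is kept as a named parameter because the two are
  conceptually distinct probes (strand periodicity vs polar/apolar face
  alternation)
* EBSS, a strand-face score:  max over the two alternation phases of
  (1/L) sum log p_face(i)(a_i), where even-parity positions face the lipid
  (outward propensities) and odd-parity the pore (inward), or vice versa.

The per-peptide maximum and minimum of each parameter over all windows give
the 10-component extrema vector; a 5-bit combination mask picks either the
max or min of each parameter as one coordinate of a 5-D point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from io import StringIO
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .pools import PeptidePool, PeptideRecord
from .scales import AA_ALPHABETICAL, HydrophobicityScale

WINDOW_LENGTH_DEFAULT = 10

#: The ten extrema in table-index order (even = max, odd = min).
PARAMETER_NAMES = (
    "max_ebss", "min_ebss",
    "max_alternating", "min_alternating",
    "max_moment_alpha", "min_moment_alpha",
    "max_moment_beta", "min_moment_beta",
    "max_average", "min_average",
)

#: Fixed parameter order used by combination masks.
PARAMETER_ORDER = ("ebss", "alternating", "moment_alpha", "moment_beta", "average")

MOMENT_ALPHA_DEG = 100.0
MOMENT_BETA_DEG = 180.0


class ParamError(ValueError):
    pass


@dataclass(frozen=True)
class EbssPropensities:
    """Positive outward (lipid-facing) / inward (pore-facing) propensities.

    The bundled default is a synthetic stand-in table that reproduces the
    qualitative behaviour of published beta-barrel face propensities —
    hydrophobic residues score on the lipid face, polar ones on the pore
    face — without being an exact transform of any bundled hydrophobicity
    scale (an antisymmetric exp(+-beta*h) construction would make the score
    collinear with the alternating hydrophobicity of that same scale and
    collapse one cloud dimension).  Published tables can be loaded with
    ``from_table``.
    """

    outward: Mapping[str, float]
    inward: Mapping[str, float]

    def __post_init__(self) -> None:
        for name, table in (("outward", self.outward), ("inward", self.inward)):
            if set(table) != set(AA_ALPHABETICAL):
                raise ParamError(f"{name} propensities must cover the 20 amino acids")
            if any(v <= 0 for v in table.values()):
                raise ParamError(f"{name} propensities must be strictly positive")

    @classmethod
    def neutral(cls) -> "EbssPropensities":
        """All-ones table: EBSS is identically zero (useful in tests only)."""
        ones = {a: 1.0 for a in AA_ALPHABETICAL}
        return cls(outward=dict(ones), inward=dict(ones))

    @classmethod
    def synthetic_from_scale(cls, scale: HydrophobicityScale, beta: float = 0.25) -> "EbssPropensities":
        return cls(
            outward={a: math.exp(beta * v) for a, v in scale.values.items()},
            inward={a: math.exp(-beta * v) for a, v in scale.values.items()},
        )

    @classmethod
    def default(cls) -> "EbssPropensities":
        return cls(outward=dict(_SYNTHETIC_OUTWARD), inward=dict(_SYNTHETIC_INWARD))

    @classmethod
    def from_table(cls, text: str) -> "EbssPropensities":
        """TSV with columns (aa, outward, inward)."""
        df = pd.read_csv(StringIO(text), sep="\t", comment="#")
        return cls(
            outward=dict(zip(df["aa"], df["outward"].astype(float))),
            inward=dict(zip(df["aa"], df["inward"].astype(float))),
        )


# Synthetic beta-barrel face propensities (dimensionless, stand-in values):
# lipid-facing (outward) positions favour apolar residues, pore-facing
# (inward) positions favour polar/charged ones.
_SYNTHETIC_OUTWARD = {
    "A": 1.30, "C": 1.60, "D": 0.40, "E": 0.35, "F": 2.20,
    "G": 0.90, "H": 0.50, "I": 2.40, "K": 0.30, "L": 2.30,
    "M": 1.70, "N": 0.45, "P": 0.60, "Q": 0.45, "R": 0.30,
    "S": 0.70, "T": 0.80, "V": 2.20, "W": 1.90, "Y": 1.40,
}
_SYNTHETIC_INWARD = {
    "A": 0.90, "C": 0.80, "D": 1.30, "E": 1.25, "F": 0.60,
    "G": 1.40, "H": 1.10, "I": 0.50, "K": 1.35, "L": 0.55,
    "M": 0.70, "N": 1.30, "P": 0.80, "Q": 1.25, "R": 1.30,
    "S": 1.50, "T": 1.40, "V": 0.60, "W": 0.70, "Y": 1.00,
}


def _hvalues(window: str, scale: HydrophobicityScale) -> np.ndarray:
    vals = []
    for pos, aa in enumerate(window):
        try:
            vals.append(scale.values[aa])
        except KeyError:
            raise ParamError(
                f"unknown residue {aa!r} at position {pos} for scale {scale.id!r}"
            ) from None
    return np.array(vals)


def average_hydrophobicity(window: str, scale: HydrophobicityScale) -> float:
    """Mean scale value over the window."""
    if not window:
        raise ParamError("empty window")
    return float(_hvalues(window, scale).mean())


def hydrophobic_moment(window: str, scale: HydrophobicityScale, delta: float) -> float:
    """Length-normalised hydrophobic moment at angular offset *delta* (degrees)."""
    if not window:
        raise ParamError("empty window")
    h = _hvalues(window, scale)
    i = np.arange(len(h))
    d = math.radians(delta)
    return float(np.hypot((h * np.sin(i * d)).sum(), (h * np.cos(i * d)).sum()) / len(h))


def alternating_hydrophobicity(window: str, scale: HydrophobicityScale) -> float:
    """(1/L) |sum (-1)^i h_i| — polar/apolar face alternation."""
    if len(window) < 2:
        raise ParamError("alternating hydrophobicity needs a window of length >= 2")
    h = _hvalues(window, scale)
    signs = np.where(np.arange(len(h)) % 2 == 0, 1.0, -1.0)
    return float(abs((signs * h).sum()) / len(h))


def ebss(window: str, propensities: EbssPropensities) -> float:
    """Phase-maximised mean log face propensity of the window (L >= 10)."""
    L = len(window)
    if L < WINDOW_LENGTH_DEFAULT:
        raise ParamError(f"EBSS needs at least {WINDOW_LENGTH_DEFAULT} residues, got {L}")
    try:
        lo = np.array([math.log(propensities.outward[a]) for a in window])
        li = np.array([math.log(propensities.inward[a]) for a in window])
    except KeyError as e:
        raise ParamError(f"unknown residue {e.args[0]!r}") from None
    even = np.arange(L) % 2 == 0
    s0 = (lo[even].sum() + li[~even].sum()) / L
    s1 = (li[even].sum() + lo[~even].sum()) / L
    return float(max(s0, s1))


@dataclass(frozen=True)
class ParameterVector:
    """The ten per-peptide extrema in table-index order."""

    peptide_id: str
    scale_id: str
    extrema: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.extrema) != 10:
            raise ParamError("extrema vector must have 10 components")
        for k in range(5):
            if self.extrema[2 * k] < self.extrema[2 * k + 1] - 1e-12:
                raise ParamError(
                    f"extrema[{2 * k}] (max) < extrema[{2 * k + 1}] (min) "
                    f"for {PARAMETER_ORDER[k]}"
                )


def window_extrema(
    peptide: PeptideRecord | str,
    scale: HydrophobicityScale,
    ebss_propensities: EbssPropensities | None = None,
    window_len: int = WINDOW_LENGTH_DEFAULT,
    peptide_id: str | None = None,
) -> ParameterVector:
    """Slide a window of *window_len* (step 1) and record max/min of each parameter."""
    if ebss_propensities is None:
        ebss_propensities = EbssPropensities.default()
    seq = peptide if isinstance(peptide, str) else peptide.sequence
    pid = peptide_id or (peptide if isinstance(peptide, str) else peptide.id)
    L = window_len
    if len(seq) < L:
        raise ParamError(
            f"peptide {pid!r} (length {len(seq)}) shorter than window length {L}"
        )
    h = _hvalues(seq, scale)
    lo = np.array([math.log(ebss_propensities.outward[a]) for a in seq])
    li = np.array([math.log(ebss_propensities.inward[a]) for a in seq])

    wh = sliding_window_view(h, L)
    i = np.arange(L)
    signs = np.where(i % 2 == 0, 1.0, -1.0)

    avg = wh.mean(axis=1)
    alt = np.abs(wh @ signs) / L
    da = math.radians(MOMENT_ALPHA_DEG)
    mom_a = np.hypot(wh @ np.sin(i * da), wh @ np.cos(i * da)) / L
    db = math.radians(MOMENT_BETA_DEG)
    mom_b = np.hypot(wh @ np.sin(i * db), wh @ np.cos(i * db)) / L
    even = signs > 0
    wlo = sliding_window_view(lo, L)
    wli = sliding_window_view(li, L)
    s0 = (wlo[:, even].sum(axis=1) + wli[:, ~even].sum(axis=1)) / L
    s1 = (wli[:, even].sum(axis=1) + wlo[:, ~even].sum(axis=1)) / L
    eb = np.maximum(s0, s1)

    ext = (
        eb.max(), eb.min(),
        alt.max(), alt.min(),
        mom_a.max(), mom_a.min(),
        mom_b.max(), mom_b.min(),
        avg.max(), avg.min(),
    )
    return ParameterVector(peptide_id=pid, scale_id=scale.id, extrema=tuple(map(float, ext)))


def select_combination(v: ParameterVector, combo: int) -> np.ndarray:
    """5-D point: bit k of *combo* picks max (0) or min (1) of parameter k."""
    if not (0 <= combo <= 31):
        raise ParamError(f"combination mask {combo} outside 0..31")
    return np.array(
        [v.extrema[2 * k + ((combo >> k) & 1)] for k in range(5)], dtype=float
    )


def pool_points(
    pool: PeptidePool,
    scale: HydrophobicityScale,
    combo: int,
    ebss_propensities: EbssPropensities | None = None,
    window_len: int = WINDOW_LENGTH_DEFAULT,
) -> np.ndarray:
    """5-D points for every peptide of a pool long enough for the window."""
    if ebss_propensities is None:
        ebss_propensities = EbssPropensities.default()
    pts = [
        select_combination(
            window_extrema(rec, scale, ebss_propensities, window_len), combo
        )
        for rec in pool.records
        if len(rec) >= window_len
    ]
    return np.array(pts) if pts else np.empty((0, 5))


def parameter_table(
    pool: PeptidePool,
    scale: HydrophobicityScale,
    ebss_propensities: EbssPropensities | None = None,
    window_len: int = WINDOW_LENGTH_DEFAULT,
) -> pd.DataFrame:
    """Long-format extrema table (one row per peptide, ten named columns)."""
    if ebss_propensities is None:
        ebss_propensities = EbssPropensities.default()
    rows = []
    for rec in pool.records:
        if len(rec) < window_len:
            continue
        pv = window_extrema(rec, scale, ebss_propensities, window_len)
        row = {"peptide_id": pv.peptide_id, "scale_id": pv.scale_id}
        row.update(dict(zip(PARAMETER_NAMES, pv.extrema)))
        rows.append(row)
    return pd.DataFrame(rows, columns=["peptide_id", "scale_id", *PARAMETER_NAMES])
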