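"""Seeded synthetic generator of annotated proteins and peptide pools.

The generator emulates the statistical structure the separation analysis
assumes: transmembrane helices are strongly hydrophobic, transmembrane
strands alternate apolar (lipid-facing) and polar (pore-facing) residues,
soluble helix/sheet segments use moderately distinct soluble compositions
and coil is uniform background.  K/R spacers between segments make the
in-silico tryptic digest recover segments, and k-mer motifs can be planted
at controlled per-segment rates with a ground-truth ledger.

Everything is driven by one integer seed; per-protein RNG streams are
spawned deterministically so output is byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .pools import MIN_PEPTIDE_LENGTH, PeptidePool, PeptideRecord
from .scales import AA_ALPHABETICAL

KINDS = ("tm_helix", "tm_sheet", "s_helix", "s_sheet", "coil")

_KIND_SSE = {"tm_helix": "H", "tm_sheet": "E", "s_helix": "H", "s_sheet": "E", "coil": "C"}
_KIND_TOPO = {"tm_helix": "M", "tm_sheet": "M", "s_helix": "S", "s_sheet": "S", "coil": "S"}
_KIND_POOL = {
    "tm_helix": "tm-helix", "tm_sheet": "tm-sheet",
    "s_helix": "s-helix", "s_sheet": "s-sheet", "coil": "random",
}


class SyntheticError(ValueError):
    pass


def _profile(weights: dict[str, float]) -> np.ndarray:
    """Dense 20-vector (alphabetical order) from a sparse weight dict; residues
    not named share a small uniform floor."""
    floor = 0.2 / 20.0
    v = np.full(20, floor)
    for aa, w in weights.items():
        v[AA_ALPHABETICAL.index(aa)] += w
    return v / v.sum()


#: Strongly hydrophobic profile (TM helices, lipid-facing strand positions).
HYDROPHOBIC_PROFILE = _profile(
    {"L": 0.20, "I": 0.14, "V": 0.13, "F": 0.11, "A": 0.11, "M": 0.05, "G": 0.04, "W": 0.02}
)
#: Polar profile (pore-facing strand positions, spacers of soluble segments).
POLAR_PROFILE = _profile(
    {"D": 0.10, "E": 0.10, "K": 0.10, "R": 0.08, "N": 0.10, "Q": 0.10, "S": 0.11, "T": 0.11}
)
#: Soluble helix-former bias (mild: soluble pools share most of their
#: composition, unlike the strongly constrained membrane segments).
S_HELIX_PROFILE = _profile(
    {"A": 0.05, "E": 0.05, "L": 0.05, "K": 0.04, "Q": 0.03, "R": 0.03}
)
#: Soluble strand-former bias (mild, see above).
S_SHEET_PROFILE = _profile(
    {"V": 0.05, "I": 0.04, "Y": 0.03, "T": 0.04, "F": 0.03, "S": 0.03, "G": 0.02}
)
#: Coil: uniform background.
COIL_PROFILE = np.full(20, 1.0 / 20.0)

DEFAULT_PROFILES = {
    "tm_helix": HYDROPHOBIC_PROFILE,
    "tm_sheet": 0.5 * HYDROPHOBIC_PROFILE + 0.5 * POLAR_PROFILE,  # marginal composition
    "s_helix": S_HELIX_PROFILE,
    "s_sheet": S_SHEET_PROFILE,
    "coil": COIL_PROFILE,
}


@dataclass(frozen=True)
class SegmentPlan:
    kind: str
    min_len: int
    max_len: int

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise SyntheticError(f"unknown segment kind {self.kind!r}")
        if not (1 <= self.min_len <= self.max_len):
            raise SyntheticError(
                f"infeasible plan: segment {self.kind} length bounds "
                f"[{self.min_len}, {self.max_len}]"
            )


@dataclass(frozen=True)
class MotifPlant:
    pattern: str
    target_kind: str
    prob: float

    def __post_init__(self) -> None:
        if self.target_kind not in KINDS:
            raise SyntheticError(f"unknown motif target kind {self.target_kind!r}")
        if not (0.0 <= self.prob <= 1.0):
            raise SyntheticError(f"planting probability {self.prob} outside [0,1]")
        if set(self.pattern) - set(AA_ALPHABETICAL):
            raise SyntheticError(f"motif {self.pattern!r} uses non-standard residues")


@dataclass(frozen=True)
class SyntheticSpec:
    seed: int
    n_proteins: int
    segment_plan: tuple[SegmentPlan, ...]
    kr_spacer_rate: float = 0.5
    motif_plants: tuple[MotifPlant, ...] = ()
    composition_profiles: dict | None = None  # kind -> 20-vector override
    # sub-profiles used for the alternating TM-sheet positions
    hydrophobic_profile: np.ndarray = field(default_factory=lambda: HYDROPHOBIC_PROFILE)
    polar_profile: np.ndarray = field(default_factory=lambda: POLAR_PROFILE)

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise SyntheticError("n_proteins must be >= 1")
        if not self.segment_plan:
            raise SyntheticError("segment plan is empty")
        if not (0.0 <= self.kr_spacer_rate <= 1.0):
            raise SyntheticError("kr_spacer_rate outside [0,1]")
        for plant in self.motif_plants:
            fits = any(
                p.kind == plant.target_kind and p.min_len >= len(plant.pattern)
                for p in self.segment_plan
            )
            if not fits:
                raise SyntheticError(
                    f"infeasible plan: motif {plant.pattern!r} does not fit any "
                    f"{plant.target_kind} segment"
                )
        if self.composition_profiles is not None:
            for kind, prof in self.composition_profiles.items():
                p = np.asarray(prof, float)
                if abs(p.sum() - 1.0) > 1e-9:
                    raise SyntheticError(f"profile for {kind!r} does not sum to 1")

    def profile(self, kind: str) -> np.ndarray:
        if self.composition_profiles and kind in self.composition_profiles:
            return np.asarray(self.composition_profiles[kind], float)
        return DEFAULT_PROFILES[kind]


_AA_ARR = np.array(list(AA_ALPHABETICAL))


def _sample_segment(kind: str, length: int, spec: SyntheticSpec, rng: np.random.Generator) -> str:
    if kind == "tm_sheet":
        # alternate lipid-facing (even) / pore-facing (odd) positions
        hp = spec.composition_profiles.get("tm_sheet_even", spec.hydrophobic_profile) \
            if spec.composition_profiles else spec.hydrophobic_profile
        pp = spec.composition_profiles.get("tm_sheet_odd", spec.polar_profile) \
            if spec.composition_profiles else spec.polar_profile
        res = [
            _AA_ARR[rng.choice(20, p=hp if i % 2 == 0 else pp)] for i in range(length)
        ]
        return "".join(res)
    prof = spec.profile(kind)
    return "".join(_AA_ARR[rng.choice(20, p=prof, size=length)])


def generate_proteins(spec: SyntheticSpec) -> tuple[list[PeptideRecord], dict]:
    """Generate annotated proteins plus a ground-truth ledger.

    The ledger records, per protein, the (kind, start, end) coordinates of
    every segment (0-based half-open, post spacer insertion) and the motif
    planting positions.
    """
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_proteins)
    records: list[PeptideRecord] = []
    ledger: dict = {"seed": spec.seed, "proteins": {}, "plant_counts": {}}
    for p_idx, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        seq_parts: list[str] = []
        sse_parts: list[str] = []
        topo_parts: list[str] = []
        segments: list[dict] = []
        pos = 0
        for s_idx, plan in enumerate(spec.segment_plan):
            length = int(rng.integers(plan.min_len, plan.max_len + 1))
            seg_seq = _sample_segment(plan.kind, length, spec, rng)
            # motif planting: overwrite residues, keep annotation
            plants = []
            for plant in spec.motif_plants:
                if plant.target_kind != plan.kind or len(plant.pattern) > length:
                    continue
                if rng.random() < plant.prob:
                    start = int(rng.integers(0, length - len(plant.pattern) + 1))
                    seg_seq = (
                        seg_seq[:start] + plant.pattern + seg_seq[start + len(plant.pattern):]
                    )
                    plants.append({"pattern": plant.pattern, "pos": pos + start})
                    ledger["plant_counts"][plant.pattern] = (
                        ledger["plant_counts"].get(plant.pattern, 0) + 1
                    )
            seq_parts.append(seg_seq)
            sse_parts.append(_KIND_SSE[plan.kind] * length)
            topo_parts.append(_KIND_TOPO[plan.kind] * length)
            segments.append(
                {"kind": plan.kind, "start": pos, "end": pos + length, "plants": plants}
            )
            pos += length
            if s_idx < len(spec.segment_plan) - 1 and rng.random() < spec.kr_spacer_rate:
                spacer = "K" if rng.random() < 0.5 else "R"
                seq_parts.append(spacer)
                sse_parts.append("C")
                topo_parts.append("S")
                pos += 1
        rec = PeptideRecord(
            id=f"syn{p_idx:05d}",
            sequence="".join(seq_parts),
            sse="".join(sse_parts),
            topo="".join(topo_parts),
        )
        records.append(rec)
        ledger["proteins"][rec.id] = segments
    return records, ledger


# ---------------------------------------------------------------------------
# pool pairs for the separation stages

def generate_pool_pair(
    kind_a: str,
    kind_b: str,
    n_per_pool: int,
    separation_strength: float,
    seed: int,
    min_len: int = 15,
    max_len: int = 30,
) -> tuple[PeptidePool, PeptidePool, dict]:
    """Two single-kind pools with controllable compositional separation.

    At *separation_strength* 0 both pools sample from the midpoint of the two
    kinds' composition profiles (exchangeable distributions); at 1 each pool
    uses its own full profile.  Intermediate values interpolate linearly.
    """
    if kind_a not in KINDS or kind_b not in KINDS:
        raise SyntheticError(f"unknown kinds ({kind_a!r}, {kind_b!r})")
    if n_per_pool < 12:
        raise SyntheticError(
            f"n_per_pool = {n_per_pool} too small: a 5-D hull needs well over "
            "6 points per pool (minimum 12)"
        )
    if not (0.0 <= separation_strength <= 1.0):
        raise SyntheticError("separation_strength outside [0,1]")

    def kind_profile(kind: str, pos: int) -> np.ndarray:
        """Position-wise composition of a pure segment of *kind*."""
        if kind == "tm_sheet":
            return HYDROPHOBIC_PROFILE if pos % 2 == 0 else POLAR_PROFILE
        return DEFAULT_PROFILES[kind]

    # Symmetric position-wise interpolation: weight (1+s)/2 on the pool's
    # own kind, (1-s)/2 on the partner's, so strength 0 gives both pools
    # the identical midpoint distribution (exchangeable) and strength 1 the
    # full kind-specific profiles.
    s = separation_strength

    pools: list[PeptidePool] = []
    streams = np.random.SeedSequence(seed).spawn(2)
    for kind, other, stream, tag in (
        (kind_a, kind_b, streams[0], "a"),
        (kind_b, kind_a, streams[1], "b"),
    ):
        w = (1.0 + s) / 2.0
        rng = np.random.default_rng(stream)
        recs = []
        for i in range(n_per_pool):
            length = int(rng.integers(min_len, max_len + 1))
            seq = "".join(
                _AA_ARR[rng.choice(
                    20,
                    p=w * kind_profile(kind, pos) + (1 - w) * kind_profile(other, pos),
                )]
                for pos in range(length)
            )
            recs.append(
                PeptideRecord(
                    id=f"{tag}{i:04d}",
                    sequence=seq,
                    sse=_KIND_SSE[kind] * length,
                    topo=_KIND_TOPO[kind] * length,
                )
            )
        pools.append(PeptidePool(label=_KIND_POOL[kind], records=recs, strategy="structure"))
    ledger = {
        "kind_a": kind_a, "kind_b": kind_b, "n_per_pool": n_per_pool,
        "separation_strength": separation_strength, "seed": seed,
        "min_len": min_len, "max_len": max_len,
    }
    return pools[0], pools[1], ledger


#: Synthetic stand-ins for the five digest-derived evaluation pools of the
#: scale optimiser, mapped onto the generator's segment kinds.
EVAL_POOL_KINDS = {
    "dd-helix": "s_helix",
    "dd-sheet": "s_sheet",
    "dd-random": "coil",
    "krtm-helix": "tm_helix",
    "krtm-sheet": "tm_sheet",
}


def generate_eval_pools(
    n_per_pool: int = 40,
    separation_strength: float = 1.0,
    seed: int = 0,
    min_len: int = 15,
    max_len: int = 30,
) -> dict[str, PeptidePool]:
    """Five synthetic pools emulating the digest-derived evaluation set.

    Each pool's position-wise composition interpolates between the global
    mixture of all five kinds (*separation_strength* 0: all pools identical)
    and its own kind profile (*separation_strength* 1).
    """
    if n_per_pool < 12:
        raise SyntheticError(
            f"n_per_pool = {n_per_pool} too small for 5-D hulls (minimum 12)"
        )
    if not (0.0 <= separation_strength <= 1.0):
        raise SyntheticError("separation_strength outside [0,1]")

    def kind_profile(kind: str, pos: int) -> np.ndarray:
        if kind == "tm_sheet":
            return HYDROPHOBIC_PROFILE if pos % 2 == 0 else POLAR_PROFILE
        return DEFAULT_PROFILES[kind]

    kinds = list(EVAL_POOL_KINDS.values())
    s = separation_strength
    pools: dict[str, PeptidePool] = {}
    streams = np.random.SeedSequence(seed).spawn(len(EVAL_POOL_KINDS))
    for (label, kind), stream in zip(EVAL_POOL_KINDS.items(), streams):
        rng = np.random.default_rng(stream)
        recs = []
        for i in range(n_per_pool):
            length = int(rng.integers(min_len, max_len + 1))
            seq = []
            for pos in range(length):
                mixture = np.mean([kind_profile(k, pos) for k in kinds], axis=0)
                p = s * kind_profile(kind, pos) + (1 - s) * mixture
                seq.append(_AA_ARR[rng.choice(20, p=p)])
            recs.append(
                PeptideRecord(
                    id=f"{label}-{i:04d}",
                    sequence="".join(seq),
                    sse=_KIND_SSE[kind] * length,
                    topo=_KIND_TOPO[kind] * length,
                )
            )
        pools[label] = PeptidePool(label=label, records=recs, strategy="digest")
    return pools
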