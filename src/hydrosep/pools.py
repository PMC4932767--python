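"""Peptide pool construction from annotated protein sequences.

Two complementary strategies generate the 17 canonical pools:

* *structure dissection* — maximal runs of a single secondary-structure
  element (SSE) become peptides, split into soluble (s-helix, s-sheet,
  random) and transmembrane (tm-helix, tm-sheet) pools; and
* *in-silico tryptic digestion* — cleavage after every K and R followed by
  classification of each fragment by its dominating SSE (continuous dc-*,
  discontinuous dd-*), by the absent SSE when no element dominates (no-*),
  as ``all`` when all three elements occur without dominance, or as a
  transmembrane fragment (krtm-helix, krtm-sheet) whenever membrane-annotated
  residues are present.

Every pooled peptide is at least 10 residues long (the minimum window for
the strand-face score) and pools are deduplicated on exact sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from io import StringIO
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .scales import AA_ALPHABETICAL

MIN_PEPTIDE_LENGTH = 10
DOMINANCE_DEFAULT = 0.70

SSE_ALPHABET = "HEC"
TOPO_ALPHABET = "MS"

STRUCTURE_POOL_LABELS = ("random", "s-sheet", "s-helix", "tm-sheet", "tm-helix")
DIGEST_POOL_LABELS = (
    "dc-helix", "dc-sheet", "dc-random",
    "dd-helix", "dd-sheet", "dd-random",
    "no-helix", "no-sheet", "no-random",
    "all", "krtm-helix", "krtm-sheet",
)
POOL_LABELS = STRUCTURE_POOL_LABELS + DIGEST_POOL_LABELS

_SSE_TO_WORD = {"H": "helix", "E": "sheet", "C": "random"}


class PoolError(ValueError):
    pass


@dataclass(frozen=True)
class PeptideRecord:
    """A sequence with per-residue SSE ({H,E,C}) and topology ({M,S}) strings."""

    id: str
    sequence: str
    sse: str
    topo: str

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if n < 1:
            raise PoolError(f"record {self.id!r}: empty sequence")
        if len(self.sse) != n or len(self.topo) != n:
            raise PoolError(
                f"record {self.id!r}: annotation lengths "
                f"({len(self.sse)}, {len(self.topo)}) != sequence length {n}"
            )
        bad = set(self.sequence) - set(AA_ALPHABETICAL)
        if bad:
            raise PoolError(f"record {self.id!r}: non-standard residues {sorted(bad)}")
        if set(self.sse) - set(SSE_ALPHABET):
            raise PoolError(f"record {self.id!r}: SSE letters outside {{H,E,C}}")
        if set(self.topo) - set(TOPO_ALPHABET):
            raise PoolError(f"record {self.id!r}: topology letters outside {{M,S}}")

    def __len__(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int, suffix: str) -> "PeptideRecord":
        """Sub-record over the 0-based half-open interval [start, end)."""
        return PeptideRecord(
            id=f"{self.id}{suffix}",
            sequence=self.sequence[start:end],
            sse=self.sse[start:end],
            topo=self.topo[start:end],
        )


@dataclass
class PeptidePool:
    label: str
    records: list[PeptideRecord] = field(default_factory=list)
    strategy: str = "structure"  # or "digest"

    def __len__(self) -> int:
        return len(self.records)

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]


# ---------------------------------------------------------------------------
# structure dissection

def dissect_sse_segments(protein: PeptideRecord) -> list[tuple[PeptideRecord, str]]:
    """Split a protein into maximal single-SSE segments and label them.

    Soluble runs map to s-helix / s-sheet / random and are discarded when
    shorter than 10 residues.  Runs containing any membrane residue map to
    tm-helix / tm-sheet and, when shorter than 10, are padded with flanking
    residues of the parent (alternating right then left) until they reach 10.
    Membrane-annotated coil runs have no pool and are dropped.
    """
    out: list[tuple[PeptideRecord, str]] = []
    n = len(protein)
    i = 0
    seg_no = 0
    while i < n:
        j = i
        while j < n and protein.sse[j] == protein.sse[i]:
            j += 1
        letter = protein.sse[i]
        is_tm = "M" in protein.topo[i:j]
        start, end = i, j
        label: str | None
        if is_tm:
            if letter == "H":
                label = "tm-helix"
            elif letter == "E":
                label = "tm-sheet"
            else:
                label = None  # membrane coil: no pool defined
            if label is not None and end - start < MIN_PEPTIDE_LENGTH:
                start, end = _extend_to_min(start, end, n)
        else:
            label = {"H": "s-helix", "E": "s-sheet", "C": "random"}[letter]
            if end - start < MIN_PEPTIDE_LENGTH:
                label = None
        if label is not None and end - start >= MIN_PEPTIDE_LENGTH:
            out.append((protein.slice(start, end, f"|seg{seg_no}"), label))
        seg_no += 1
        i = j
    return out


def _extend_to_min(start: int, end: int, n: int, minlen: int = MIN_PEPTIDE_LENGTH) -> tuple[int, int]:
    """Grow [start, end) to *minlen* by alternating right/left extension."""
    grow_right = True
    while end - start < minlen and (start > 0 or end < n):
        if grow_right and end < n:
            end += 1
        elif start > 0:
            start -= 1
        elif end < n:
            end += 1
        grow_right = not grow_right
    return start, end


# ---------------------------------------------------------------------------
# tryptic digestion & classification

def tryptic_digest(protein: PeptideRecord) -> list[PeptideRecord]:
    """Cleave after every K and R; fragments partition the sequence in order."""
    frags: list[PeptideRecord] = []
    start = 0
    idx = 0
    for i, aa in enumerate(protein.sequence):
        if aa in ("K", "R"):
            frags.append(protein.slice(start, i + 1, f"|kr{idx}"))
            start = i + 1
            idx += 1
    if start < len(protein):
        frags.append(protein.slice(start, len(protein), f"|kr{idx}"))
    return frags


def classify_fragment(frag: PeptideRecord, dominance: float = DOMINANCE_DEFAULT) -> str | None:
    """Assign a digest-pool label to a fragment, or None if shorter than 10.

    Rule order: membrane content wins (krtm-helix / krtm-sheet by the
    majority SSE among membrane residues); otherwise a strictly dominating
    SSE (> *dominance* of residues) gives dc-* if its occurrences are one
    contiguous block, dd-* otherwise; otherwise exactly two SSE letters give
    the no-* label of the absent one; otherwise ``all``.
    """
    n = len(frag)
    if n < MIN_PEPTIDE_LENGTH:
        return None
    if "M" in frag.topo:
        m_sse = [frag.sse[i] for i in range(n) if frag.topo[i] == "M"]
        n_h = m_sse.count("H")
        n_e = m_sse.count("E")
        # tie (including all-coil membrane residues) resolves to helix
        return "krtm-sheet" if n_e > n_h else "krtm-helix"
    counts = {c: frag.sse.count(c) for c in SSE_ALPHABET}
    for letter in SSE_ALPHABET:
        if counts[letter] / n > dominance:
            first = frag.sse.find(letter)
            last = frag.sse.rfind(letter)
            contiguous = (last - first + 1) == counts[letter]
            prefix = "dc" if contiguous else "dd"
            return f"{prefix}-{_SSE_TO_WORD[letter]}"
    present = [c for c in SSE_ALPHABET if counts[c] > 0]
    if len(present) == 2:
        absent = next(c for c in SSE_ALPHABET if counts[c] == 0)
        return f"no-{_SSE_TO_WORD[absent]}"
    return "all"


# ---------------------------------------------------------------------------
# orchestration

def assemble_pools(
    proteins: Sequence[PeptideRecord], dominance: float = DOMINANCE_DEFAULT
) -> dict[str, PeptidePool]:
    """Run both strategies over all proteins and build the 17 pools.

    Pools are deduplicated on exact peptide sequence (first occurrence kept).
    Empty pools are present in the returned map so downstream accounting sees
    all labels.
    """
    if not proteins:
        warnings.warn("assemble_pools: empty input, all pools empty")
    pools = {
        label: PeptidePool(label=label, strategy="structure")
        for label in STRUCTURE_POOL_LABELS
    }
    pools.update(
        {label: PeptidePool(label=label, strategy="digest") for label in DIGEST_POOL_LABELS}
    )
    seen: dict[str, set[str]] = {label: set() for label in POOL_LABELS}
    for protein in proteins:
        for segment, label in dissect_sse_segments(protein):
            if segment.sequence not in seen[label]:
                seen[label].add(segment.sequence)
                pools[label].records.append(segment)
        for frag in tryptic_digest(protein):
            label = classify_fragment(frag, dominance=dominance)
            if label is None:
                continue
            if frag.sequence not in seen[label]:
                seen[label].add(frag.sequence)
                pools[label].records.append(frag)
    return pools


def pool_summary(pools: dict[str, PeptidePool]) -> pd.DataFrame:
    """Per-pool peptide count and mean length (mirrors the pool inventory tables)."""
    rows = []
    for label, pool in pools.items():
        lengths = [len(r) for r in pool.records]
        rows.append(
            {
                "pool": label,
                "strategy": pool.strategy,
                "n_peptides": len(pool),
                "mean_length": float(pd.Series(lengths).mean()) if lengths else 0.0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# IO

def read_annotated_fasta(fasta_text: str, annotation_tsv: str) -> list[PeptideRecord]:
    """Read sequences from FASTA and per-residue annotations from a TSV with
    columns (id, sse, topo)."""
    ann = pd.read_csv(StringIO(annotation_tsv), sep="\t", dtype=str, comment="#")
    ann = ann.set_index("id")
    records = []
    for rec in SeqIO.parse(StringIO(fasta_text), "fasta"):
        if rec.id not in ann.index:
            raise PoolError(f"no annotation row for sequence {rec.id!r}")
        row = ann.loc[rec.id]
        records.append(
            PeptideRecord(id=rec.id, sequence=str(rec.seq), sse=row["sse"], topo=row["topo"])
        )
    return records


def read_combined_tsv(text: str) -> list[PeptideRecord]:
    """Read records from a single TSV with columns (id, sequence, sse, topo)."""
    df = pd.read_csv(StringIO(text), sep="\t", dtype=str, comment="#")
    return [
        PeptideRecord(id=r["id"], sequence=r["sequence"], sse=r["sse"], topo=r["topo"])
        for _, r in df.iterrows()
    ]


def records_to_fasta(records: Iterable[PeptideRecord]) -> str:
    buf = StringIO()
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records),
        buf,
        "fasta",
    )
    return buf.getvalue()


def records_to_annotation_tsv(records: Iterable[PeptideRecord]) -> str:
    lines = ["id\tsse\ttopo"]
    lines += [f"{r.id}\t{r.sse}\t{r.topo}" for r in records]
    return "\n".join(lines) + "\n"
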