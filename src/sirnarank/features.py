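"""The 497-dimensional siRNA feature space.

Every 19-nt antisense guide strand is encoded into one ordered vector of 497
descriptors spanning the feature families known to matter for silencing
efficacy: position-dependent nucleotide identity, short sequence motifs,
GC-content thresholds, nearest-neighbor duplex thermodynamics,
immune-stimulatory motifs, palindromes, homopolymer stretches and
intramolecular secondary structure.

Block layout of the default schema (1-based feature indices):

====== ==========================================================
1      constant (doubles as the unpenalised intercept column)
2–77   nucleotide identity, A/G/U/C × PS1..PS19 (one-hot per position)
78–93  2-mer presence anywhere in PS[1..19]
94–157 3-mer presence
158–413 4-mer presence
414–431 dinucleotide stack ΔG°37 at PS[i, i+1], i = 1..18
432–447 summed stack ΔG over 4-nt windows PS[i..i+3]
448–459 summed stack ΔG over 8-nt windows PS[i..i+7]
460–466 whole-duplex ΔG, 5'/3' terminal asymmetry, half-duplex ΔGs,
        extreme and mean stack ΔG
467–470 immune-stimulatory motif and palindrome flags
471–476 homopolymer stretch flags (G/C/A/U ≥ 3; G/C ≥ 4)
477–485 GC content lower bounds '>0.05' … '>0.45' (0.05 grid)
486–494 GC content upper bounds '<0.95' … '<0.55' (0.05 grid)
495–497 secondary structure: paired fraction, long-stem flag, hairpin flag
====== ==========================================================

Nucleotide and k-mer blocks are ordered over the alphabet **A, G, U, C**
(nucleotide-major), which places e.g. 'A @ PS1' at index 2, 'U @ PS1' at 40,
'GG in PS[1,2]' at 414 and 'UCU in PS[1..19]' at 140 — the indices used in
the published cross-platform ranking.

The schema is a versioned, machine-readable manifest
(:meth:`FeatureSchema.to_json`) so the composition can be amended without
code changes.  Several reconstruction choices (the identity of feature 1,
the exact GC grid, scalar-vs-flag structure features) are marked
``reconstruction_uncertain`` in descriptor parameters.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io_datasets import SIRNA_LENGTH, reverse_complement
from .structure import structure_content
from .thermo import stack_profile

SCHEMA_VERSION = "1.0"

#: Alphabet order shared by the positional and k-mer blocks.
NUC_ORDER = "AGUC"

#: Immune-stimulatory motif flags: the canonical 'UGUGU' (TLR7/8 trigger)
#: and the 9-mer 'GUCCUUCAA' sense-strand danger motif.
IMMUNE_MOTIFS = ("UGUGU", "GUCCUUCAA")

N_FEATURES = 497


class EncodingError(Exception):
    """A sequence cannot be encoded under a schema."""


@dataclass(frozen=True)
class FeatureDescriptor:
    index: int  # 1-based, contiguous
    name: str
    category: str  # positional | motif | gc | thermo | structure | misc
    kind: str  # evaluator dispatch key
    params: dict = field(default_factory=dict)


@dataclass
class FeatureSchema:
    """Ordered manifest of feature descriptors."""

    descriptors: list[FeatureDescriptor]
    version: str = SCHEMA_VERSION

    def __post_init__(self):
        idx = [d.index for d in self.descriptors]
        if idx != list(range(1, len(idx) + 1)):
            raise ValueError("descriptor indices must be contiguous from 1")

    def __len__(self) -> int:
        return len(self.descriptors)

    def names(self) -> list[str]:
        return [d.name for d in self.descriptors]

    def __getitem__(self, index: int) -> FeatureDescriptor:
        """Descriptor by 1-based feature index."""
        return self.descriptors[index - 1]

    def index_of(self, name: str) -> int:
        for d in self.descriptors:
            if d.name == name:
                return d.index
        raise KeyError(name)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "version": self.version,
            "descriptors": [
                {"index": d.index, "name": d.name, "category": d.category,
                 "kind": d.kind, "params": d.params}
                for d in self.descriptors
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "FeatureSchema":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        return cls(
            [FeatureDescriptor(**d) for d in payload["descriptors"]],
            version=payload.get("version", SCHEMA_VERSION),
        )


def gc_content(seq: str) -> float:
    """Fraction of G/C over the full 19-mer."""
    return (seq.count("G") + seq.count("C")) / len(seq)


def motif_presence(seq: str, motif: str) -> int:
    """1 iff ``motif`` occurs as a contiguous substring of ``seq``."""
    return int(motif in seq)


def has_stretch(seq: str, nt: str, min_len: int) -> int:
    return int(nt * min_len in seq)


def has_palindrome(seq: str, min_len: int) -> int:
    """1 iff some contiguous substring of length ≥ ``min_len`` equals its own
    RNA reverse complement.  Such substrings necessarily have even length."""
    L = min_len + (min_len % 2)
    for length in range(L, len(seq) + 1, 2):
        for start in range(len(seq) - length + 1):
            sub = seq[start : start + length]
            if sub == reverse_complement(sub):
                return 1
    return 0


def _kmer_names(k: int) -> list[str]:
    return ["".join(p) for p in itertools.product(NUC_ORDER, repeat=k)]


def _build_descriptors() -> list[FeatureDescriptor]:
    d: list[FeatureDescriptor] = []

    def add(name: str, category: str, kind: str, **params) -> None:
        d.append(FeatureDescriptor(len(d) + 1, name, category, kind, params))

    add("constant", "misc", "constant", reconstruction_uncertain=True)

    for nt in NUC_ORDER:
        for pos in range(1, SIRNA_LENGTH + 1):
            add(f"{nt} @ PS{pos}", "positional", "positional", nt=nt, pos=pos)

    for k in (2, 3, 4):
        for motif in _kmer_names(k):
            add(f"{motif} in PS[1..{SIRNA_LENGTH}]", "motif", "kmer", motif=motif)

    for i in range(1, SIRNA_LENGTH):
        add(f"GG in PS[{i},{i + 1}]", "thermo", "stack", i=i)

    for i in range(1, SIRNA_LENGTH - 2):  # 16 windows of width 4
        add(f"dG PS[{i}..{i + 3}]", "thermo", "window_dg", start=i, stop=i + 3)
    for i in range(1, SIRNA_LENGTH - 6):  # 12 windows of width 8
        add(f"dG PS[{i}..{i + 7}]", "thermo", "window_dg", start=i, stop=i + 7)

    add("dG PS[1..19]", "thermo", "window_dg", start=1, stop=SIRNA_LENGTH)
    add("dG asymmetry PS[1,2]-PS[18,19]", "thermo", "dg_asymmetry")
    add("dG PS[1..10]", "thermo", "window_dg", start=1, stop=10)
    add("dG PS[10..19]", "thermo", "window_dg", start=10, stop=SIRNA_LENGTH)
    add("min stack dG", "thermo", "stack_min")
    add("max stack dG", "thermo", "stack_max")
    add("mean stack dG", "thermo", "stack_mean")

    for motif in IMMUNE_MOTIFS:
        add(f"immune motif {motif}", "misc", "kmer", motif=motif)
    add("palindrome of length >=6", "misc", "palindrome", min_len=6)
    add("palindrome of length >=8", "misc", "palindrome", min_len=8)

    for nt, min_len in (("G", 3), ("C", 3), ("A", 3), ("U", 3), ("G", 4), ("C", 4)):
        add(f"{nt} stretch of length >={min_len}", "motif", "stretch", nt=nt, min_len=min_len)

    for t in range(1, 10):  # >0.05 .. >0.45
        add(f"GC content>{t * 0.05:g}", "gc", "gc_gt", threshold=round(t * 0.05, 2),
            reconstruction_uncertain=True)
    for t in range(19, 10, -1):  # <0.95 down to <0.55
        add(f"GC content<{t * 0.05:g}", "gc", "gc_lt", threshold=round(t * 0.05, 2),
            reconstruction_uncertain=True)

    add("paired fraction", "structure", "paired_fraction", reconstruction_uncertain=True)
    add("max stem of length >=5", "structure", "max_stem_flag", min_len=5,
        reconstruction_uncertain=True)
    add("hairpin present", "structure", "hairpin_flag", reconstruction_uncertain=True)
    return d


@lru_cache(maxsize=1)
def build_default_schema() -> FeatureSchema:
    """The deterministic default 497-feature schema described above."""
    schema = FeatureSchema(_build_descriptors())
    assert len(schema) == N_FEATURES
    return schema


def _validate(seq: str) -> None:
    if len(seq) != SIRNA_LENGTH:
        raise EncodingError(f"expected a {SIRNA_LENGTH}-nt sequence, got {len(seq)}")
    if any(c not in "ACGU" for c in seq):
        raise EncodingError(f"sequence {seq!r} is not over A/C/G/U")


def encode(seq: str, schema: FeatureSchema | None = None) -> np.ndarray:
    """Encode one normalised antisense sequence into its feature vector.

    Pure and deterministic: identical (sequence, schema) pairs always give
    bit-identical vectors.
    """
    return encode_many([seq], schema)[0]


def encode_many(
    seqs: Sequence[str] | Iterable[str], schema: FeatureSchema | None = None
) -> np.ndarray:
    """Encode many sequences into an (n, len(schema)) design matrix."""
    schema = schema or build_default_schema()
    seqs = list(seqs)
    out = np.empty((len(seqs), len(schema)), dtype=float)
    needs_structure = any(
        d.kind in ("paired_fraction", "max_stem_flag", "hairpin_flag")
        for d in schema.descriptors
    )
    for row, seq in enumerate(seqs):
        _validate(seq)
        stacks = stack_profile(seq)
        gc = gc_content(seq)
        struct = structure_content(seq) if needs_structure else None
        for col, d in enumerate(schema.descriptors):
            out[row, col] = _evaluate(d, seq, stacks, gc, struct)
    return out


def _evaluate(d: FeatureDescriptor, seq, stacks, gc, struct) -> float:
    kind, p = d.kind, d.params
    if kind == "constant":
        return 1.0
    if kind == "positional":
        return float(seq[p["pos"] - 1] == p["nt"])
    if kind == "kmer":
        return float(p["motif"] in seq)
    if kind == "stack":
        return float(stacks[p["i"] - 1])
    if kind == "window_dg":
        return float(stacks[p["start"] - 1 : p["stop"] - 1].sum())
    if kind == "dg_asymmetry":
        return float(stacks[0] - stacks[-1])
    if kind == "stack_min":
        return float(stacks.min())
    if kind == "stack_max":
        return float(stacks.max())
    if kind == "stack_mean":
        return float(stacks.mean())
    if kind == "palindrome":
        return float(has_palindrome(seq, p["min_len"]))
    if kind == "stretch":
        return float(has_stretch(seq, p["nt"], p["min_len"]))
    if kind == "gc_gt":
        return float(gc > p["threshold"])
    if kind == "gc_lt":
        return float(gc < p["threshold"])
    if kind == "paired_fraction":
        return struct.paired_fraction
    if kind == "max_stem_flag":
        return float(struct.max_stem >= p["min_len"])
    if kind == "hairpin_flag":
        return float(struct.hairpin_flag)
    raise EncodingError(f"unknown descriptor kind {kind!r}")  # pragma: no cover
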