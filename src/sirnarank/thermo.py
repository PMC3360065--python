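"""RNA nearest-neighbor duplex thermodynamics.

Stacking free energies ΔG°37 (kcal/mol) for Watson–Crick nearest-neighbor
steps from Xia et al. (1998) *Biochemistry* 37:14719–14735 ("Thermodynamic
parameters for an expanded nearest-neighbor model for formation of RNA
duplexes with Watson-Crick base pairs").

The published table lists 10 unique stacks; the remaining 6 of the 16
dinucleotide steps follow from the symmetry that a 5'XY3' step and its
reverse-complement step describe the same physical stack:

    value(XY) == value(reverse_complement(XY))

A step is keyed by the 5'→3' dinucleotide on one strand; the opposite strand
is the Watson–Crick complement.  More negative = more stable.
"""

from __future__ import annotations

import numpy as np

from .io_datasets import reverse_complement

#: Xia-1998 ΔG°37 (kcal/mol) for all 16 Watson–Crick dinucleotide steps,
#: keyed by the 5'→3' dinucleotide of one strand.
XIA1998_STACK_DG37: dict[str, float] = {
    "AA": -0.93, "UU": -0.93,
    "AU": -1.10,
    "UA": -1.33,
    "CU": -2.08, "AG": -2.08,
    "CA": -2.11, "UG": -2.11,
    "GU": -2.24, "AC": -2.24,
    "GA": -2.35, "UC": -2.35,
    "CG": -2.36,
    "GG": -3.26, "CC": -3.26,
    "GC": -3.42,
}

assert len(XIA1998_STACK_DG37) == 16
assert all(
    XIA1998_STACK_DG37[k] == XIA1998_STACK_DG37[reverse_complement(k)]
    for k in XIA1998_STACK_DG37
)


def dinucleotide_stability(seq: str, i: int) -> float:
    """ΔG°37 of the duplex stack formed by positions ``i`` and ``i+1``.

    ``i`` is 1-based on the antisense strand (so ``i`` ranges over 1..18 for
    a 19-mer); the value is the nearest-neighbor stacking free energy of
    ``seq[i-1:i+1]`` paired with its Watson–Crick complement.
    """
    if not 1 <= i <= len(seq) - 1:
        raise ValueError(f"stack index {i} out of range 1..{len(seq) - 1}")
    dimer = seq[i - 1 : i + 1]
    try:
        return XIA1998_STACK_DG37[dimer]
    except KeyError:
        raise ValueError(f"non-ACGU dinucleotide {dimer!r} at position {i}")


def stack_profile(seq: str) -> np.ndarray:
    """All ``len(seq) - 1`` consecutive stack ΔG°37 values, 5'→3'."""
    return np.array([dinucleotide_stability(seq, i) for i in range(1, len(seq))])


def window_dg(seq: str, start: int, stop: int) -> float:
    """Summed stack ΔG°37 over antisense positions ``start..stop`` (1-based,
    inclusive): the duplex free energy of that window up to end effects."""
    if not 1 <= start < stop <= len(seq):
        raise ValueError(f"bad window [{start}, {stop}] for length {len(seq)}")
    return float(sum(dinucleotide_stability(seq, i) for i in range(start, stop)))
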