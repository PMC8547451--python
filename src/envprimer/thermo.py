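"""Primer melting temperature and base composition.

Two Tm estimators are provided.  The default is the unified
nearest-neighbor model (SantaLucia, PNAS 1998): duplex ΔH°/ΔS° summed over
dinucleotide stacks with terminal initiation terms, an entropic
monovalent-salt correction ``ΔS += 0.368·(N−1)·ln[Na+]``, and

    Tm = 1000·ΔH° / (ΔS° + R·ln(CT/x)) − 273.15

with R = 1.987 cal/(K·mol), total strand concentration CT = 200 nM and
x = 4 for non-self-complementary duplexes (x = 1, with a −1.4 cal/(K·mol)
symmetry term, for self-complementary ones).  The Wallace rule
``2(A+T) + 4(G+C)`` is kept as a quick sanity estimator for short oligos.
"""

from __future__ import annotations

import math

from .seqio import reverse_complement

R_GAS = 1.987  # cal / (K mol)
PRIMER_CONC_M = 200e-9  # total strand concentration, 200 nM

# SantaLucia 1998 unified parameters: (ΔH kcal/mol, ΔS cal/(K mol)).
_NN = {
    "AA": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
_INIT_GC = (0.1, -2.8)  # duplex end on a G·C pair
_INIT_AT = (2.3, 4.1)   # duplex end on an A·T pair
_SYM = (0.0, -1.4)      # self-complementary symmetry correction


def gc_percent(seq: str) -> float:
    """G+C content of a nondegenerate DNA string, in percent."""
    if not seq:
        raise ValueError("empty sequence")
    return 100.0 * sum(1 for b in seq if b in "GC") / len(seq)


def tm_wallace(seq: str) -> float:
    """Wallace rule: 2 °C per A/T, 4 °C per G/C."""
    _check_nondegenerate(seq)
    return float(sum(2 if b in "AT" else 4 for b in seq))


def tm_nearest_neighbor(seq: str, na_mM: float = 50.0) -> float:
    """Unified nearest-neighbor Tm in °C at the given monovalent Na+ (mM)."""
    _check_nondegenerate(seq)
    if len(seq) < 2:
        raise ValueError("nearest-neighbor Tm needs length >= 2")
    if na_mM <= 0:
        raise ValueError("Na+ concentration must be positive")

    dh, ds = 0.0, 0.0
    for end in (seq[0], seq[-1]):
        h, s = _INIT_GC if end in "GC" else _INIT_AT
        dh += h
        ds += s
    for i in range(len(seq) - 1):
        pair = seq[i : i + 2]
        if pair not in _NN:
            pair = reverse_complement(pair)
        h, s = _NN[pair]
        dh += h
        ds += s

    selfcomp = seq == reverse_complement(seq)
    if selfcomp:
        dh += _SYM[0]
        ds += _SYM[1]
    ds += 0.368 * (len(seq) - 1) * math.log(na_mM / 1000.0)
    conc = PRIMER_CONC_M if selfcomp else PRIMER_CONC_M / 4.0
    return 1000.0 * dh / (ds + R_GAS * math.log(conc)) - 273.15


def melting_temp(seq: str, method: str = "nearest_neighbor", na_mM: float = 50.0) -> float:
    """Tm of a nondegenerate primer by the chosen method.

    Degenerate primers have no single Tm; expand them first and evaluate
    each form (a degenerate base here raises).
    """
    if method == "nearest_neighbor":
        return tm_nearest_neighbor(seq, na_mM=na_mM)
    if method == "wallace":
        return tm_wallace(seq)
    raise ValueError(f"unknown Tm method {method!r}")


def _check_nondegenerate(seq: str) -> None:
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(
            f"degenerate/invalid base(s) {sorted(bad)}: expand IUPAC codes before Tm"
        )
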