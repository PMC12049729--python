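"""Genetic code and trinucleotide mutation-context machinery.

Single-base substitutions in coding sequence are classified by their
*mutation context*: the substituted base together with one base upstream
and one base downstream, written ``X[R>A]Y``.  On the coding strand there
are 12 substitutions x 16 flank pairs = 192 raw contexts.  Collapsing
strand-symmetric pairs (reverse-complementing contexts whose reference
base is a purine) yields the familiar 96 substitution classes.
"""

from __future__ import annotations

import re

import numpy as np
from Bio.Seq import Seq

BASES = "ACGT"
BASE_CODE = {b: i for i, b in enumerate(BASES)}
# A<->T, C<->G under code complement: comp(code) == 3 - code
PYRIMIDINE_CODES = (1, 3)  # C, T

_CTX_RE = re.compile(r"^([ACGT])\[([ACGT])>([ACGT])\]([ACGT])$")


def _make_contexts(refs: str) -> list[str]:
    out = []
    for ref in refs:
        for alt in BASES:
            if alt == ref:
                continue
            for up in BASES:
                for dn in BASES:
                    out.append(f"{up}[{ref}>{alt}]{dn}")
    return out


#: canonical orderings; index arithmetic in :func:`context_index` matches these
CONTEXTS_192 = _make_contexts(BASES)
CONTEXTS_96 = _make_contexts("CT")
CONTEXT_192_INDEX = {c: i for i, c in enumerate(CONTEXTS_192)}
CONTEXT_96_INDEX = {c: i for i, c in enumerate(CONTEXTS_96)}

# 64-entry codon -> amino acid table (standard genetic code), indexed by
# 16*c0 + 4*c1 + c2 over base codes.
CODON_AA = np.array(
    [str(Seq(a + b + c).translate(table=1)) for a in BASES for b in BASES for c in BASES]
)


def _alt_rank(ref_code: np.ndarray, alt_code: np.ndarray) -> np.ndarray:
    """Rank of the alternate base among the three non-reference bases."""
    return alt_code - (alt_code > ref_code)


def context_index_192(up, ref, alt, dn):
    """Vectorised 192-context index from base codes (A=0,C=1,G=2,T=3)."""
    up, ref, alt, dn = (np.asarray(x) for x in (up, ref, alt, dn))
    return ((ref * 3 + _alt_rank(ref, alt)) * 4 + up) * 4 + dn


def context_index_96(up, ref, alt, dn):
    """Vectorised pyrimidine-collapsed context index from base codes.

    Contexts whose reference base is a purine are reverse-complemented
    (flanks swapped and complemented) before indexing.
    """
    up, ref, alt, dn = (np.asarray(x, dtype=np.int64) for x in (up, ref, alt, dn))
    purine = (ref == 0) | (ref == 2)
    up_c = np.where(purine, 3 - dn, up)
    dn_c = np.where(purine, 3 - up, dn)
    ref_c = np.where(purine, 3 - ref, ref)
    alt_c = np.where(purine, 3 - alt, alt)
    ref96 = (ref_c == 3).astype(np.int64)  # C -> 0, T -> 1
    return ((ref96 * 3 + _alt_rank(ref_c, alt_c)) * 4 + up_c) * 4 + dn_c


def collapse_context(context: str) -> str:
    """Collapse a 192-scheme context string to its 96-scheme class."""
    m = _CTX_RE.match(context)
    if m is None:
        raise ValueError(f"malformed context string: {context!r}")
    up, ref, alt, dn = m.groups()
    idx = context_index_96(*(BASE_CODE[b] for b in (up, ref, alt, dn)))
    return CONTEXTS_96[int(idx)]


def encode_sequence(seq: str) -> np.ndarray:
    """DNA string -> int8 codes; raises on characters outside ACGT."""
    table = np.full(256, -1, dtype=np.int8)
    for b, i in BASE_CODE.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    codes = table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        bad = sorted(set(seq) - set("ACGTacgt"))
        raise ValueError(f"sequence contains non-ACGT characters: {bad}")
    return codes


def translate_codes(codes: np.ndarray) -> str:
    """Translate an in-frame coding sequence given as base codes."""
    codons = codes.reshape(-1, 3)
    idx = codons[:, 0] * 16 + codons[:, 1] * 4 + codons[:, 2]
    return "".join(CODON_AA[idx])
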