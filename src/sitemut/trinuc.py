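"""Trinucleotide (SBS96) encoding shared by the interval and mutation machinery.

Single-base substitutions are normalized to the pyrimidine strand: a mutation
whose reference base is A or G is reported as the reverse complement of its
context and alleles.  This yields 32 pyrimidine-centred trinucleotide contexts
(16 around C, 16 around T) and 96 substitution classes, plus one pooled indel
class.  Class ids follow the COSMIC catalogue ordering: six substitution blocks
C>A, C>G, C>T, T>A, T>C, T>G, each holding the 16 flanking-base combinations in
A, C, G, T order.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
A, C, G, T, N = 0, 1, 2, 3, 4

#: byte -> base code lookup (case-insensitive; everything else maps to N)
BASE_CODE = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    BASE_CODE[ord(_b)] = _i
    BASE_CODE[ord(_b.lower())] = _i

#: complement of a base code (N stays N)
COMPLEMENT = np.array([T, G, C, A, N], dtype=np.uint8)

PYRIMIDINE_SUBS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

N_CONTEXTS = 32
N_SNV_CLASSES = 96
INDEL_CLASS = 96
N_CLASSES = 97

#: class ids of sentinel states on mutation records
CLASS_UNCLASSIFIED = -2
CLASS_EXCLUDED = -1


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 code array."""
    return BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


def _build_context_tables():
    """125-entry triplet -> context lookup, computed once from first principles."""
    ctx = np.full(125, -1, dtype=np.int8)
    flip = np.zeros(125, dtype=bool)
    for left in range(5):
        for centre in range(5):
            for right in range(5):
                if N in (left, centre, right):
                    continue
                flipped = centre in (A, G)
                if flipped:
                    l2, c2, r2 = COMPLEMENT[right], COMPLEMENT[centre], COMPLEMENT[left]
                else:
                    l2, c2, r2 = left, centre, right
                key = (left * 5 + centre) * 5 + right
                ctx[key] = (c2 == T) * 16 + l2 * 4 + r2
                flip[key] = flipped
    return ctx, flip


_CTX_TABLE, _FLIP_TABLE = _build_context_tables()


def context_index(left: np.ndarray, centre: np.ndarray, right: np.ndarray):
    """Pyrimidine-normalized context index for base-code triplets.

    Returns ``(ctx, flipped)`` where ``ctx`` is in ``0..31`` (or -1 where any
    base is N) and ``flipped`` marks triplets that were reverse-complemented
    because the centre base is a purine.  ``ctx = 16*(centre is T) + 4*left +
    right`` in pyrimidine-strand orientation.
    """
    key = (
        np.asarray(left, dtype=np.int32) * 5 + np.asarray(centre, dtype=np.int32)
    ) * 5 + np.asarray(right, dtype=np.int32)
    return _CTX_TABLE[key].astype(np.int64), _FLIP_TABLE[key]


def class_from_context(ctx: np.ndarray, alt_pyr: np.ndarray) -> np.ndarray:
    """SBS96 class id for a context index and pyrimidine-strand alt base code.

    For contexts centred on C the three alternatives A, G, T map to the C>A,
    C>G, C>T blocks; for T-centred contexts A, C, G map to T>A, T>C, T>G.
    """
    ctx = np.asarray(ctx, dtype=np.int64)
    alt_pyr = np.asarray(alt_pyr, dtype=np.int64)
    centre_is_t = ctx // 16
    ref = np.where(centre_is_t == 1, T, C)
    rank = alt_pyr - (alt_pyr > ref)
    return (3 * centre_is_t + rank) * 16 + ctx % 16


#: (32, 3) map from context index to its three SNV class ids
CONTEXT_CLASSES = np.empty((N_CONTEXTS, 3), dtype=np.int64)
for _ctx in range(N_CONTEXTS):
    _ref = T if _ctx >= 16 else C
    _alts = [b for b in range(4) if b != _ref]
    CONTEXT_CLASSES[_ctx] = [class_from_context(_ctx, a) for a in _alts]

#: (96,) map from class id to pyrimidine-strand alt base code
CLASS_ALT_PYR = np.empty(N_SNV_CLASSES, dtype=np.uint8)
#: (96,) map from class id to its context index
CLASS_CONTEXT = np.empty(N_SNV_CLASSES, dtype=np.int64)
for _ctx in range(N_CONTEXTS):
    _ref = T if _ctx >= 16 else C
    _alts = [b for b in range(4) if b != _ref]
    for _a in _alts:
        _k = int(class_from_context(_ctx, _a))
        CLASS_ALT_PYR[_k] = _a
        CLASS_CONTEXT[_k] = _ctx


def class_label(class_id: int) -> str:
    """Human-readable label, e.g. ``A[C>T]G`` or ``indel``."""
    if class_id == INDEL_CLASS:
        return "indel"
    sub = class_id // 16
    lr = class_id % 16
    ref, alt = PYRIMIDINE_SUBS[sub].split(">")
    return f"{BASES[lr // 4]}[{ref}>{alt}]{BASES[lr % 4]}"


CLASS_LABELS = tuple(class_label(k) for k in range(N_CLASSES))
CLASS_ID = {lab: k for k, lab in enumerate(CLASS_LABELS)}

#: class id -> pyrimidine-normalized substitution string ("C>A".."T>G", indel -> None)
CLASS_REFALT = tuple(
    PYRIMIDINE_SUBS[k // 16] if k < N_SNV_CLASSES else None for k in range(N_CLASSES)
)
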