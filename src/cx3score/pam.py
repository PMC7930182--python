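"""CDR3 pairwise alignment scores and distances (PAM10, linear gap penalty).

Global Needleman-Wunsch alignment of CDR3 amino-acid sequences under a
low-divergence PAM10 log-odds matrix with a flat penalty per gap position
(default 30, i.e. -30 per indel symbol; no separate extension cost). The
packaged matrix is derived once by the Dayhoff chain from the 1978
relatedness-odds data and frozen (scripts/make_pam10.py); its checksum is
asserted at load time.

The pairwise distance is self-score-normalised,

    d(a, b) = 1 - S(a, b) / sqrt(S(a, a) * S(b, b)),

which is symmetric and zero at identity; strongly dissimilar pairs with a
negative cross-score give d > 1.
"""

from __future__ import annotations

import hashlib
from functools import lru_cache
from importlib import resources

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import ValidationError
from .repertoire import DistanceMatrix

DEFAULT_GAP = 30.0
PAM10_SHA256 = "632c631dfe34c3ae72a222f1a239ac6037ad948203971081b51bdd0ac9ac98fe"
_ALPHABET = "ARNDCQEGHILKMFPSTWYV"


@lru_cache(maxsize=1)
def load_pam10():
    """The packaged PAM10 substitution matrix (checksummed)."""
    ref = resources.files("cx3score.data") / "pam10.txt"
    text = ref.read_text()
    digest = hashlib.sha256(text.encode()).hexdigest()
    if digest != PAM10_SHA256:
        raise ValidationError(f"pam10.txt checksum mismatch: {digest}")
    with resources.as_file(ref) as path:
        return substitution_matrices.read(str(path))


def _check_sequence(seq: str, name: str) -> None:
    if not seq:
        raise ValidationError(f"sequence {name} is empty")
    for pos, residue in enumerate(seq):
        if residue not in _ALPHABET:
            raise ValidationError(
                f"unknown residue {residue!r} at position {pos} of sequence {name}"
            )


@lru_cache(maxsize=8)
def _aligner(gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = load_pam10()
    aligner.open_gap_score = -gap
    aligner.extend_gap_score = -gap
    return aligner


def pam10_align(a: str, b: str, gap: float = DEFAULT_GAP) -> float:
    """Optimal global alignment score of two CDR3 amino-acid sequences."""
    _check_sequence(a, "a")
    _check_sequence(b, "b")
    return float(_aligner(float(gap)).score(a, b))


def self_score(a: str, gap: float = DEFAULT_GAP) -> float:
    """Alignment score of a sequence against itself (PAM10 diagonal sum)."""
    return pam10_align(a, a, gap)


def seq_distance(a: str, b: str, gap: float = DEFAULT_GAP) -> float:
    """Self-score-normalised alignment distance; 0 iff identical arguments."""
    if a == b:
        _check_sequence(a, "a")
        return 0.0
    s_aa = self_score(a, gap)
    s_bb = self_score(b, gap)
    if s_aa <= 0 or s_bb <= 0:
        raise ValidationError("non-positive self-alignment score")
    return float(1.0 - pam10_align(a, b, gap) / np.sqrt(s_aa * s_bb))


def distance_matrix(sequences, frequencies=None, gap: float = DEFAULT_GAP) -> DistanceMatrix:
    """Pairwise seq_distance matrix over unique CDR3 sequences.

    frequencies, when given, are attached as leaf weights for
    frequency-weighted dendrograms.
    """
    seqs = list(sequences)
    if len(set(seqs)) != len(seqs):
        raise ValidationError("sequences must be unique")
    n = len(seqs)
    d = np.zeros((n, n))
    selfs = [self_score(s, gap) for s in seqs]
    for i in range(n):
        for j in range(i + 1, n):
            s_ab = pam10_align(seqs[i], seqs[j], gap)
            d[i, j] = d[j, i] = 1.0 - s_ab / np.sqrt(selfs[i] * selfs[j])
    w = np.asarray(frequencies, dtype=float) if frequencies is not None else None
    return DistanceMatrix(labels=seqs, matrix=d, weights=w)
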