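"""Fragment encoding: composition, position-weight-matrix conservation and
physicochemical information entropy.

A length-L fragment (L = 9 by default) is encoded as a 129-dimensional vector
with three blocks:

**Composition (37 dims).**  For each of the five annotation tracks the
class-frequency profile over the window, counts divided by L.  Class counts
include the pad class, giving 21 (amino acids incl. 'X') + 4 (secondary
structure H/E/C + PAD) + 5 (RSA I-IV + PAD) + 3 (phi I/II + PAD) + 4
(psi I-III + PAD) = 37 dimensions.

**Conservation (2·L·5 = 90 dims).**  Two position weight matrices per track —
one fitted on the positive training fragments, one on the negative — score
each window site.  The matrix element for class j at site i is the log-odds

    m_ij = ln(p_ij / p0_j),   p_ij = (n_ij + sqrt(N_i)/q) / (N_i + sqrt(N_i)),

where n_ij counts class j at site i over the training fragments, N_i is the
number of training fragments, and q the class count (21, 4, 5, 3, 4 — pads
are first-class symbols).  p0_j is the background probability of class j,
by default the pseudo-count-smoothed empirical frequency over all sites of
the combined (positive + negative) training fragments; ``background="uniform"``
uses 1/q instead.  A fragment contributes, per track, its L positive-matrix
scores followed by its L negative-matrix scores.

**Entropy (2 dims).**  Shannon entropy (base 2) of the fragment's real
(non-pad) residues over the 6 hydropathy classes and over the 3 charge
classes.  The pseudo-count in p_ij makes the PWM probabilities strictly
positive; the entropy block instead drops zero-probability terms exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .discretize import (
    ALPHABET,
    CHARGE_CLASSES,
    HYDROPATHY_CLASSES,
    PAD_RESIDUE,
    PHI_CLASSES,
    PSI_CLASSES,
    RSA_CLASSES,
    SS_CLASSES,
    charge_class,
    hydropathy_class,
)
from .fragments import Fragment

#: Track order used everywhere (composition blocks, conservation blocks).
TRACKS = ("aa", "ss", "rsa", "phi", "psi")

TRACK_CLASSES: dict[str, tuple[str, ...]] = {
    "aa": tuple(ALPHABET),
    "ss": SS_CLASSES,
    "rsa": RSA_CLASSES,
    "phi": PHI_CLASSES,
    "psi": PSI_CLASSES,
}

_TRACK_ATTR = {
    "aa": "residues",
    "ss": "ss_tokens",
    "rsa": "rsa_class",
    "phi": "phi_class",
    "psi": "psi_class",
}

_TRACK_INDEX = {
    track: {c: j for j, c in enumerate(classes)}
    for track, classes in TRACK_CLASSES.items()
}


def track_tokens(fragment: Fragment, track: str) -> tuple[str, ...]:
    """The fragment's token sequence on one annotation track."""
    return getattr(fragment, _TRACK_ATTR[track])


def composition_dim() -> int:
    return sum(len(TRACK_CLASSES[t]) for t in TRACKS)


def feature_dim(L: int = 9) -> int:
    """Total encoded dimensionality: composition + 2·L·5 conservation + 2 entropy."""
    return composition_dim() + 2 * L * len(TRACKS) + 2


def composition_features(fragment: Fragment) -> np.ndarray:
    """Concatenated per-track class frequencies (counts / L), 37 dims at any L."""
    L = len(fragment)
    parts = []
    for track in TRACKS:
        idx = _TRACK_INDEX[track]
        counts = np.zeros(len(idx))
        for tok in track_tokens(fragment, track):
            try:
                counts[idx[tok]] += 1
            except KeyError:
                raise ValueError(f"token {tok!r} not a {track} class") from None
        parts.append(counts / L)
    return np.concatenate(parts)


@dataclass(frozen=True)
class PositionWeightMatrix:
    """Per-site log-odds scores for one annotation track fitted on one class."""

    track: str
    fitted_on: str  # "positive" | "negative"
    L: int
    q: int
    p: np.ndarray   # L x q pseudo-count probabilities
    p0: np.ndarray  # length-q background probabilities
    m: np.ndarray   # L x q log-odds ln(p / p0)

    def score(self, tokens) -> np.ndarray:
        """Log-odds score of each window site given its observed class."""
        if len(tokens) != self.L:
            raise ValueError(f"fragment length {len(tokens)} != PWM window {self.L}")
        idx = _TRACK_INDEX[self.track]
        return np.array([self.m[i, idx[tok]] for i, tok in enumerate(tokens)])


def _count_matrix(fragments, track: str) -> np.ndarray:
    classes = TRACK_CLASSES[track]
    idx = _TRACK_INDEX[track]
    L = len(fragments[0])
    n = np.zeros((L, len(classes)))
    for frag in fragments:
        toks = track_tokens(frag, track)
        if len(toks) != L:
            raise ValueError("fragments of mixed window length")
        for i, tok in enumerate(toks):
            n[i, idx[tok]] += 1
    return n


def background_probs(fragments, track: str, mode: str = "empirical") -> np.ndarray:
    """Background class probabilities p0 for one track.

    ``empirical``: class frequencies pooled over every site of every fragment,
    smoothed with the same sqrt(N)/q pseudo-count as the per-site
    probabilities so no class has probability zero.  ``uniform``: 1/q.
    """
    q = len(TRACK_CLASSES[track])
    if mode == "uniform":
        return np.full(q, 1.0 / q)
    if mode != "empirical":
        raise ValueError(f"unknown background mode {mode!r}")
    fragments = list(fragments)
    if not fragments:
        raise ValueError("cannot estimate background from zero fragments")
    counts = _count_matrix(fragments, track).sum(axis=0)
    N = counts.sum()
    return (counts + math.sqrt(N) / q) / (N + math.sqrt(N))


def fit_pwm(fragments, track: str, fitted_on: str = "positive",
            p0: np.ndarray | None = None) -> PositionWeightMatrix:
    """Fit the pseudo-count position weight matrix on one class of fragments.

    ``p0`` is the background distribution (defaults to uniform 1/q); pass the
    output of :func:`background_probs` for the empirical background.
    """
    fragments = list(fragments)
    if not fragments:
        raise ValueError("cannot fit a PWM on an empty training set")
    q = len(TRACK_CLASSES[track])
    L = len(fragments[0])
    n = _count_matrix(fragments, track)
    N = n.sum(axis=1, keepdims=True)  # == len(fragments) at every site
    p = (n + np.sqrt(N) / q) / (N + np.sqrt(N))
    if p0 is None:
        p0 = np.full(q, 1.0 / q)
    p0 = np.asarray(p0, dtype=float)
    if p0.shape != (q,):
        raise ValueError(f"background must have length {q}")
    m = np.log(p / p0)
    return PositionWeightMatrix(track=track, fitted_on=fitted_on, L=L, q=q,
                                p=p, p0=p0, m=m)


@dataclass(frozen=True)
class PWMSet:
    """The ten matrices (5 tracks x positive/negative) used by the encoder."""

    positive: dict[str, PositionWeightMatrix]
    negative: dict[str, PositionWeightMatrix]
    L: int
    background: str

    @classmethod
    def fit(cls, fragments, background: str = "empirical") -> "PWMSet":
        """Fit all matrices from labelled training fragments.

        Backgrounds are computed per track from the combined positive and
        negative fragments; each class's matrix is then fitted on its own
        fragments against that shared background.
        """
        fragments = list(fragments)
        pos = [f for f in fragments if f.label]
        neg = [f for f in fragments if not f.label]
        if not pos or not neg:
            raise ValueError("training fragments must contain both classes")
        L = len(fragments[0])
        pos_pwms, neg_pwms = {}, {}
        for track in TRACKS:
            p0 = background_probs(fragments, track, mode=background)
            pos_pwms[track] = fit_pwm(pos, track, "positive", p0)
            neg_pwms[track] = fit_pwm(neg, track, "negative", p0)
        return cls(positive=pos_pwms, negative=neg_pwms, L=L, background=background)


def conservation_features(fragment: Fragment, pwms: PWMSet) -> np.ndarray:
    """Per-track positive- then negative-matrix site scores; 2·L·5 dims."""
    if len(fragment) != pwms.L:
        raise ValueError(f"fragment length {len(fragment)} != PWM window {pwms.L}")
    parts = []
    for track in TRACKS:
        toks = track_tokens(fragment, track)
        parts.append(pwms.positive[track].score(toks))
        parts.append(pwms.negative[track].score(toks))
    return np.concatenate(parts)


def _class_entropy(tokens, classifier, classes) -> float:
    counts = dict.fromkeys(classes, 0)
    n_real = 0
    for tok in tokens:
        if tok == PAD_RESIDUE:
            continue
        counts[classifier(tok)] += 1
        n_real += 1
    if n_real == 0:
        raise ValueError("fragment has no real residues")
    h = 0.0
    for c in classes:
        p = counts[c] / n_real
        if p > 0:
            h -= p * math.log2(p)
    return h


def entropy_features(fragment: Fragment) -> np.ndarray:
    """(hydropathy entropy, charge entropy) over the fragment's real residues."""
    return np.array([
        _class_entropy(fragment.residues, hydropathy_class, HYDROPATHY_CLASSES),
        _class_entropy(fragment.residues, charge_class, CHARGE_CLASSES),
    ])


def encode(fragment: Fragment, pwms: PWMSet) -> np.ndarray:
    """Full feature vector: composition | conservation | entropy (129 at L=9)."""
    return np.concatenate([
        composition_features(fragment),
        conservation_features(fragment, pwms),
        entropy_features(fragment),
    ])


def encode_fragments(fragments, pwms: PWMSet) -> tuple[np.ndarray, np.ndarray]:
    """Encode a fragment collection; returns (X, y)."""
    fragments = list(fragments)
    if not fragments:
        return np.empty((0, feature_dim(pwms.L))), np.empty(0, dtype=int)
    X = np.stack([encode(f, pwms) for f in fragments])
    y = np.array([int(f.label) for f in fragments])
    return X, y


def feature_names(L: int = 9) -> list[str]:
    """Column names matching the encoding layout, for auditable output files."""
    names = []
    for track in TRACKS:
        for c in TRACK_CLASSES[track]:
            names.append(f"comp_{track}_{c}")
    for track in TRACKS:
        for side in ("pos", "neg"):
            for i in range(1, L + 1):
                names.append(f"cons_{track}_{side}_{i}")
    names += ["entropy_hydropathy", "entropy_charge"]
    return names
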