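"""Residue-centred window extraction.

Each residue of a chain becomes the center of one length-``L`` fragment
(default L = 9).  The chain is conceptually padded with (L-1)/2 pseudo
residues at both ends so terminal residues get full windows; pads carry the
residue token ``X`` and the structure-class token ``PAD``.  A fragment is
positive when its center residue is annotated as binding the metal ion.
"""

from __future__ import annotations

from dataclasses import dataclass

from .discretize import (
    PAD,
    PAD_RESIDUE,
    classify_phi,
    classify_psi,
    classify_rsa,
)
from .seqio import ProteinChain


@dataclass(frozen=True)
class Fragment:
    """A length-L residue window with discretized annotation tracks."""

    chain_id: str
    center: int  # 0-based index into the unpadded chain
    residues: tuple[str, ...]
    ss_tokens: tuple[str, ...]
    rsa_class: tuple[str, ...]
    phi_class: tuple[str, ...]
    psi_class: tuple[str, ...]
    label: bool

    def __len__(self) -> int:
        return len(self.residues)


def extract_fragments(chain: ProteinChain, L: int = 9,
                      drop_x_centers: bool = False) -> list[Fragment]:
    """Excerpt one fragment per residue of ``chain``.

    L must be odd (>= 1).  With ``drop_x_centers`` fragments whose center is
    the unknown residue 'X' are omitted; by default every residue, including
    'X', centers a fragment.
    """
    if L < 1 or L % 2 == 0:
        raise ValueError(f"window length must be a positive odd integer, got {L}")
    flank = (L - 1) // 2
    n = len(chain)

    res = [PAD_RESIDUE] * flank + list(chain.sequence) + [PAD_RESIDUE] * flank
    ss = [PAD] * flank + [str(s) for s in chain.ss] + [PAD] * flank
    rsa = [PAD] * flank + [classify_rsa(float(x)) for x in chain.rsa] + [PAD] * flank
    phi = [PAD] * flank + [classify_phi(float(x)) for x in chain.phi] + [PAD] * flank
    psi = [PAD] * flank + [classify_psi(float(x)) for x in chain.psi] + [PAD] * flank

    out = []
    for c in range(n):
        if drop_x_centers and chain.sequence[c] == PAD_RESIDUE:
            continue
        lo, hi = c, c + L  # offsets into the padded tracks
        out.append(Fragment(
            chain_id=chain.chain_id,
            center=c,
            residues=tuple(res[lo:hi]),
            ss_tokens=tuple(ss[lo:hi]),
            rsa_class=tuple(rsa[lo:hi]),
            phi_class=tuple(phi[lo:hi]),
            psi_class=tuple(psi[lo:hi]),
            label=bool(chain.binding_mask[c]),
        ))
    return out


def extract_all(chains, L: int = 9, drop_x_centers: bool = False) -> list[Fragment]:
    """Fragments of every chain, concatenated in chain order."""
    out: list[Fragment] = []
    for chain in chains:
        out.extend(extract_fragments(chain, L=L, drop_x_centers=drop_x_centers))
    return out


def count_classes(fragments) -> tuple[int, int]:
    """(n_positive, n_negative) over a fragment collection."""
    fragments = list(fragments)
    n_pos = sum(1 for f in fragments if f.label)
    return n_pos, len(fragments) - n_pos
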