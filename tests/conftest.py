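import numpy as np
import pytest

from metalbind import GeneratorConfig, PWMSet, extract_all, generate, worked_example
from metalbind.discretize import PAD, PAD_RESIDUE
from metalbind.fragments import Fragment
from metalbind.seqio import ProteinChain


def make_chain(sequence, binding=(), chain_id="c1", ss=None, rsa=None,
               phi=None, psi=None):
    """Build a ProteinChain with plain defaults for any omitted track.

    ``binding`` holds 0-based positive positions.
    """
    n = len(sequence)
    mask = np.zeros(n, dtype=bool)
    for i in binding:
        mask[i] = True
    return ProteinChain(
        chain_id=chain_id,
        sequence=sequence,
        binding_mask=mask,
        ss=np.array(list(ss) if ss else ["C"] * n),
        rsa=np.array(rsa if rsa is not None else [0.3] * n, dtype=float),
        phi=np.array(phi if phi is not None else [-60.0] * n, dtype=float),
        psi=np.array(psi if psi is not None else [-45.0] * n, dtype=float),
    )


def make_fragment(residues, label=False, chain_id="c1", center=None,
                  ss=None, rsa=None, phi=None, psi=None):
    """Build a Fragment; pads on the residue track imply PAD on every track."""
    residues = tuple(residues)
    L = len(residues)

    def track(given, real_token):
        if given is not None:
            return tuple(given)
        return tuple(PAD if r == PAD_RESIDUE else real_token for r in residues)

    return Fragment(
        chain_id=chain_id,
        center=center if center is not None else L // 2,
        residues=residues,
        ss_tokens=track(ss, "C"),
        rsa_class=track(rsa, "II"),
        phi_class=track(phi, "I"),
        psi_class=track(psi, "I"),
        label=label,
    )


@pytest.fixture(scope="session")
def worked_chains():
    return worked_example()


@pytest.fixture(scope="session")
def worked_fragments(worked_chains):
    return extract_all(worked_chains)


@pytest.fixture(scope="session")
def worked_pwms(worked_fragments):
    return PWMSet.fit(worked_fragments)


@pytest.fixture(scope="session")
def planted_chains():
    """The default planted-signal study conditions."""
    return generate(GeneratorConfig(seed=11))
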