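import numpy as np
import pandas as pd
import pytest

from grouptension import load_fixtures, load_published_table, read_smiles

#: a structurally diverse liquid pool for fitting/CV tests: homologous
#: chains alone obey exact count identities (e.g. the Alkane special group
#: equals the sum of the saturated-carbon columns), so rings, branches,
#: internal olefins, halides and nitriles are mixed in to make the design
#: matrix full rank
TRAINING_POOL = {
    "ethane": "CC", "propane": "CCC", "butane": "CCCC", "pentane": "CCCCC",
    "hexane": "CCCCCC", "heptane": "CCCCCCC", "octane": "CCCCCCCC",
    "nonane": "CCCCCCCCC", "decane": "CCCCCCCCCC", "isobutane": "CC(C)C",
    "neopentane": "CC(C)(C)C", "cyclopentane": "C1CCCC1",
    "cyclohexane": "C1CCCCC1", "methylcyclohexane": "CC1CCCCC1",
    "benzene": "c1ccccc1", "toluene": "Cc1ccccc1",
    "ethylbenzene": "CCc1ccccc1", "p-xylene": "Cc1ccc(C)cc1",
    "propylbenzene": "CCCc1ccccc1", "1-hexene": "C=CCCCC",
    "1-heptene": "C=CCCCCC", "1-octene": "C=CCCCCCC", "2-hexene": "CC=CCCC",
    "cyclohexene": "C1CCC=CC1", "1-chlorobutane": "CCCCCl",
    "1-chloropentane": "CCCCCCl", "1-chlorohexane": "CCCCCCCl",
    "bromoethane": "CCBr", "1-bromobutane": "CCCCBr",
    "1-bromopentane": "CCCCCBr", "1-iodopropane": "CCCI",
    "1-iodobutane": "CCCCI", "1-iodopentane": "CCCCCI",
    "acetonitrile": "CC#N", "propionitrile": "CCC#N",
    "butyronitrile": "CCCC#N", "valeronitrile": "CCCCC#N",
}


def training_frame(seed: int = 5) -> pd.DataFrame:
    """id/smiles/st_exp frame over TRAINING_POOL with synthetic observed
    values (smooth size trend plus noise); a pipeline fixture, not data."""
    rng = np.random.default_rng(seed)
    rows = []
    for name, smi in TRAINING_POOL.items():
        n_heavy = read_smiles(smi).n_heavy_atoms
        rows.append((name, smi, 15.0 + 0.5 * n_heavy + rng.normal(0.0, 0.3)))
    return pd.DataFrame(rows, columns=["id", "smiles", "st_exp"])


@pytest.fixture(scope="session")
def table():
    return load_published_table()


@pytest.fixture(scope="session")
def fixtures():
    return load_fixtures()


@pytest.fixture(scope="session")
def anisole():
    return read_smiles("COc1ccccc1", "anisole")


def random_alkyl_smiles(rng, n_heavy, heteroatom=None):
    """Random branched alkane SMILES, optionally with one ether oxygen.

    Built as a random tree over carbon atoms with tetravalence respected;
    used by conservation and permutation-invariance property tests.
    """
    atoms = ["C"] * n_heavy
    parents: list = [None]
    children: dict[int, list[int]] = {0: []}
    for i in range(1, n_heavy):
        avail = [
            j
            for j in range(i)
            if len(children[j]) + (0 if parents[j] is None else 1) < 4
        ]
        p = int(avail[int(rng.integers(0, len(avail)))])
        parents.append(p)
        children[p].append(i)
        children[i] = []
    if heteroatom == "ether" and n_heavy >= 3:
        # an O needs degree exactly 2: one parent and one child
        candidates = [i for i in range(1, n_heavy) if len(children[i]) == 1]
        if candidates:
            atoms[candidates[int(rng.integers(0, len(candidates)))]] = "O"

    def emit(i):
        s = atoms[i]
        kids = children[i]
        for k in kids[:-1]:
            s += f"({emit(k)})"
        if kids:
            s += emit(kids[-1])
        return s

    return emit(0)
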