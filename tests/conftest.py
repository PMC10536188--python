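import numpy as np
import pandas as pd
import pytest

from bbbkit import synthetic_data as synth

#: Printed per-system descriptor rows: (logkw, logPcw, expected dlogP, E).
TABLE3_ROWS = {
    "ISRP": (0.637, 8.995, 8.358, 1.46),
    "IAM": (1.656, 8.995, 7.339, 1.46),
    "CHOL": (2.361, 8.995, 6.634, 1.46),
}

#: Hand-evaluated logBB of the built-in model on the rows above.
EXPECTED_LOGBB = {"ISRP": -0.4377, "IAM": -0.0546, "CHOL": 0.2105}


@pytest.fixture(scope="session")
def cage_pdb_text() -> str:
    """Aromatic cage around an aliphatic ligand (toy complex fixture)."""
    return synth.gen_toy_complex()


@pytest.fixture()
def table3_csv(tmp_path):
    rows = [{"system": name, "logkw": lkw, "logPcw": lpcw, "E": e}
            for name, (lkw, lpcw, _dlp, e) in TABLE3_ROWS.items()]
    path = tmp_path / "table3.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def brute_force_contacts(structure, cutoff):
    """O(N^2) all-pairs oracle: residue -> min heavy-atom distance."""
    ligand = structure.ligand_atoms()
    result = {}
    for p in structure.protein_atoms():
        for l in ligand:
            d = float(np.linalg.norm(np.subtract(l.xyz, p.xyz)))
            key = (p.chain, p.residue_number)
            if d < result.get(key, np.inf):
                result[key] = d
    return {k: v for k, v in result.items() if v < cutoff}
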