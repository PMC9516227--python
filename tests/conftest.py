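import numpy as np
import pandas as pd
import pytest

from sheddex.io import PeptideQuantTable, ProteinQuantTable


def make_peptide_table(rows, case, ctrl, reference=None):
    """Build a PeptideQuantTable from row metadata and value matrices.

    rows: list of (protein_id, peptide, start, end); case/ctrl: arrays of
    shape (n_rows, n_samples); reference: optional per-row vector.
    """
    case = np.asarray(case, dtype=float)
    ctrl = np.asarray(ctrl, dtype=float)
    data = pd.DataFrame(rows, columns=["protein_id", "peptide", "start", "end"])
    groups = {}
    for j in range(case.shape[1]):
        col = f"case_{j + 1:02d}"
        data[col] = case[:, j]
        groups[col] = "case"
    for j in range(ctrl.shape[1]):
        col = f"control_{j + 1:02d}"
        data[col] = ctrl[:, j]
        groups[col] = "control"
    if reference is not None:
        data["reference"] = np.asarray(reference, dtype=float)
        groups["reference"] = "reference"
    return PeptideQuantTable(data=data, groups=groups)


def make_protein_table(values, n_case, n_control, index=None):
    """ProteinQuantTable from an array of log2 ratios (proteins x samples)."""
    values = np.asarray(values, dtype=float)
    cols = [f"case_{j + 1:02d}" for j in range(n_case)] + [
        f"control_{j + 1:02d}" for j in range(n_control)
    ]
    assert values.shape[1] == len(cols)
    if index is None:
        index = [f"P{i:03d}" for i in range(values.shape[0])]
    frame = pd.DataFrame(values, index=pd.Index(index, name="protein_id"),
                         columns=cols)
    groups = {c: ("case" if c.startswith("case") else "control") for c in cols}
    return ProteinQuantTable(values=frame, groups=groups)


@pytest.fixture(scope="session")
def small_catalog():
    from sheddex.simulate import generate_catalog

    return generate_catalog(30, (300, 600), seed=7)
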