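import numpy as np
import pandas as pd
import pytest

from pnec.io import ExpressionMatrix, GenePanel
from pnec.repertoire import COUNTS_POSITIVE, DetectionMatrix


def make_matrix(counts, genes=None, cells=None, cell_type="PNEC", dataset="test"):
    """Build a validated ExpressionMatrix from a 2-D array (genes × cells)."""
    counts = np.asarray(counts)
    genes = genes or [f"g{i}" for i in range(counts.shape[0])]
    cells = cells or [f"c{j}" for j in range(counts.shape[1])]
    df = pd.DataFrame(counts, index=genes, columns=cells)
    types = [cell_type] * len(cells) if isinstance(cell_type, str) else list(cell_type)
    meta = pd.DataFrame({"cell_type": types, "dataset": dataset}, index=df.columns)
    return ExpressionMatrix(counts=df, cell_meta=meta)


def make_detection(calls, genes=None, cells=None):
    """Build a DetectionMatrix from a boolean array (genes × cells)."""
    calls = np.asarray(calls, dtype=bool)
    genes = genes or [f"g{i}" for i in range(calls.shape[0])]
    cells = cells or [f"c{j}" for j in range(calls.shape[1])]
    df = pd.DataFrame(calls, index=genes, columns=cells)
    meta = pd.DataFrame({"cell_type": "PNEC", "dataset": "test"}, index=df.columns)
    return DetectionMatrix(
        calls=df,
        panel=GenePanel.from_genes(genes),
        cell_meta=meta,
        policy=COUNTS_POSITIVE,
    )


@pytest.fixture(scope="session")
def mouse_run():
    """One simulated mouse-like cohort shared across tests (seed fixed)."""
    import pnec
    from pnec import simulate as S

    spec = S.mouse_pnec_like_spec(seed=1)
    m = pnec.normalize_lncpm(S.simulate_cells(spec))
    pnecs = m.subset_cells(m.cells_of_type("PNEC"))
    det = pnec.call_detection(pnecs, spec.panel)
    return {"spec": spec, "matrix": m, "pnec": pnecs, "detection": det}
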