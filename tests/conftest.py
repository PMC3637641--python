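import numpy as np
import pandas as pd
import pytest

from rpmeta.listbuild import GeneList
from rpmeta.rankprod import CASE, CONTROL, ExpressionStudy
from rpmeta.synthetic import SimulationConfig, generate_study


def make_study(matrix, n_case, n_control, symbols=None, **kw):
    """Small ExpressionStudy around an explicit matrix."""
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    return ExpressionStudy(
        probe_ids=[f"p{i}" for i in range(n)],
        symbols=symbols or [f"G{i}" for i in range(n)],
        matrix=matrix,
        group_labels=[CASE] * n_case + [CONTROL] * n_control,
        **kw,
    )


def make_gene_list(symbols, direction="up", study="S", collapsed=True, fcs=None):
    """Collapsed GeneList with the given symbols in rank order."""
    n = len(symbols)
    entries = pd.DataFrame(
        {
            "rank": range(1, n + 1),
            "probe_id": [f"{study}_{i}" for i in range(n)],
            "symbol": list(symbols),
            "FC": fcs if fcs is not None else ([2.0] * n if direction == "up" else [0.5] * n),
            "p": [1e-5] * n,
            "pfp": [0.01] * n,
        }
    )
    return GeneList(study_name=study, direction=direction, entries=entries,
                    collapsed=collapsed, universe_size=n)


@pytest.fixture(scope="session")
def planted_study():
    """5v5 study with 2-fold planted effects, known truth, moderate noise."""
    cfg = SimulationConfig(
        n_genes=400, n_up_true=40, n_down_true=40, effect_log2fc=1.0,
        noise_sd_log2=0.25, seed=11,
    )
    return generate_study(cfg)
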