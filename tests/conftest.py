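import warnings

import numpy as np
import pandas as pd
import pytest

from methdrift import (
    BetaMatrix,
    PipelineConfig,
    SampleSheet,
    generate_annotation,
    generate_design,
    run_cascade,
    simulate_betas,
)


def make_sheet(n_reps: int = 3) -> SampleSheet:
    rows = []
    for arm in ("treated", "control"):
        for tp in ("I", "II"):
            for r in range(1, n_reps + 1):
                rows.append({"sample_id": f"{arm}_{tp}_r{r}", "arm": arm,
                             "time_point": tp, "replicate": r})
    return SampleSheet(pd.DataFrame(rows).set_index("sample_id"))


def make_matrix(values: np.ndarray, sheet: SampleSheet,
                probe_ids: list[str] | None = None) -> BetaMatrix:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    ids = probe_ids or [f"cg{i:08d}" for i in range(values.shape[0])]
    return BetaMatrix(ids, sheet.sample_ids, values)


@pytest.fixture(scope="session")
def default_config() -> PipelineConfig:
    return PipelineConfig(seed=1)


@pytest.fixture(scope="session")
def synthetic_run(default_config):
    """One medium synthetic experiment with its cascade result, shared
    across tests (the generator and cascade are deterministic)."""
    truth = generate_design(5000, seed=1)
    matrix, sheet = simulate_betas(truth, seed=1)
    annotation = generate_annotation(truth, seed=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        result = run_cascade(matrix, sheet, default_config)
    return {"truth": truth, "matrix": matrix, "sheet": sheet,
            "annotation": annotation, "result": result}
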