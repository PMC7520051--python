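import numpy as np
import pytest

from armnet.qc import filter_cells_genes, normalize_log, scale_per_sample, select_hvg
from armnet.simulate import default_design, fixture_small, simulate_dataset


@pytest.fixture(scope="session")
def small_cohort():
    """A 4-sample, 400-cells-per-sample cohort used across module tests."""
    design = default_design(
        n_samples=4, cells_per_sample=400, n_genes=1000, seed=11
    )
    cm, truth, meta = simulate_dataset(design)
    return design, cm, truth, meta


@pytest.fixture(scope="session")
def small_processed(small_cohort):
    """QC'd, normalized, HVG-flagged, per-sample-scaled version of small_cohort."""
    design, cm, truth, meta = small_cohort
    cm_qc, report = filter_cells_genes(cm)
    keep = np.isin(cm.cell_ids, cm_qc.cell_ids)
    nm = normalize_log(cm_qc)
    select_hvg(nm, 500)
    scaled = scale_per_sample(nm)
    return {
        "design": design,
        "cm": cm,
        "cm_qc": cm_qc,
        "report": report,
        "keep": keep,
        "truth": truth,
        "meta": meta,
        "nm": nm,
        "scaled": scaled,
    }


@pytest.fixture(scope="session")
def qc_fixture():
    return fixture_small()
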