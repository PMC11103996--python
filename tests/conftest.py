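import numpy as np
import pytest

import maldipept as mp


@pytest.fixture(scope="session")
def training_table() -> mp.PeakMatrix:
    """Default 50/46 synthetic training cohort (area matrix only)."""
    return mp.generate_peak_table(mp.CohortConfig(seed=20240519))


@pytest.fixture(scope="session")
def validation_table() -> mp.PeakMatrix:
    """Default 30/28 synthetic validation cohort."""
    return mp.generate_peak_table(mp.validation_cohort_config(seed=915))


@pytest.fixture(scope="session")
def rendered_cohort():
    """A rendered training cohort and its recovered peak matrix (shared by
    the slower end-to-end tests)."""
    table = mp.generate_peak_table(mp.CohortConfig(seed=7))
    spectra = mp.generate_spectra(table, mp.SpectrumRenderConfig(seed=7))
    matrix = mp.process_spectra(spectra, group_labels=table.group_labels)
    return table, spectra, matrix


def match_columns(generated: mp.PeakMatrix, recovered: mp.PeakMatrix,
                  rel_tol: float = 0.002):
    """Pairs of (generated column, recovered column) matched by m/z."""
    pairs = []
    for j, mz in enumerate(generated.reference_mzs):
        i = int(np.argmin(np.abs(recovered.reference_mzs - mz)))
        if abs(recovered.reference_mzs[i] - mz) <= rel_tol * mz:
            pairs.append((j, i))
    return pairs
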