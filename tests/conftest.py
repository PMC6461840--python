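"""Shared fixtures: one default simulated cohort and spectral data set.

Expensive artifacts (MCR fits, DE results on the default cohort) are
session-scoped so the suite pays for them once.
"""

import numpy as np
import pandas as pd
import pytest

from ecmsom.expression import test_pairwise as run_pairwise
from ecmsom.expression import test_time_course as run_time_course
from ecmsom.mcr import fit_mcr
from ecmsom.response_types import TRANSITIONS, build_hierarchy
from ecmsom.synthetic import (
    SimDesign,
    default_templates,
    make_spectral_truth,
    simulate_counts,
    simulate_spectra,
    template_truth_frame,
)


@pytest.fixture(scope="session")
def cohort():
    """Default 15-pattern template cohort with counts and metadata."""
    templates = default_templates(seed=0)
    counts, meta = simulate_counts(SimDesign(seed=1), templates)
    truth = template_truth_frame(templates)
    return {"templates": templates, "counts": counts, "meta": meta,
            "truth": truth}


@pytest.fixture(scope="session")
def cohort_hierarchy(cohort):
    annot = cohort["truth"].reset_index()[["gene_id", "category_path"]]
    return build_hierarchy(annot)


@pytest.fixture(scope="session")
def cohort_time_course(cohort):
    return run_time_course(cohort["counts"], cohort["meta"])


@pytest.fixture(scope="session")
def cohort_pairwise(cohort):
    contrasts = [("t2", "t1"), ("t3", "t2"), ("t4", "t3")]
    return {tr: run_pairwise(cohort["counts"], cohort["meta"], tx, tref)
            for tr, (tx, tref) in zip(TRANSITIONS, contrasts)}


@pytest.fixture(scope="session")
def spectral_truth():
    return make_spectral_truth(seed=0)


@pytest.fixture(scope="session")
def spectra(spectral_truth):
    return simulate_spectra(spectral_truth, seed=1)


@pytest.fixture(scope="session")
def mcr_fit_k4(spectra):
    return fit_mcr(spectra, 4, seed=1)


@pytest.fixture(scope="session")
def null_counts():
    """5000 flat genes (base 100, dispersion 0.1) for calibration checks."""
    from ecmsom.synthetic import GeneTemplate

    tpl = [GeneTemplate(gene_id=f"g{i:05d}", pattern=("S", "S", "S"),
                        base_mean=100.0, dispersion=0.1)
           for i in range(5000)]
    counts, meta = simulate_counts(SimDesign(seed=11), tpl)
    return counts, meta
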