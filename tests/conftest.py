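"""Shared fixtures: the heavy 1D-strand simulations are run once per
session and reused by the acceptance and property tests."""

import numpy as np
import pytest

from sqtpharm.cell_model import CellParams
from sqtpharm.drug_engine import get_drug
from sqtpharm.protocols import paced_biomarkers
from sqtpharm.tissue import (StrandConfig, measure_cv, measure_qt,
                             run_strand)


@pytest.fixture(scope="session")
def strand_suite():
    """Steady 1 Hz strand runs for every arm the tests need.

    Keys: (condition, arm) with arm one of None, "quin2", "diso5",
    "diso10_all", "diso10_ki".
    """
    arms = {
        ("WT", None): (None, None),
        ("SQT1", None): (None, None),
        ("SQT1", "quin2"): ("quinidine", (2.0, "all")),
        ("SQT1", "diso5"): ("disopyramide", (5.0, "all")),
        ("SQT1", "diso10_all"): ("disopyramide", (10.0, "all")),
        ("SQT1", "diso10_ki"): ("disopyramide", (10.0, "ikr+ina")),
    }
    out = {}
    for (cond, arm), (drug_name, spec) in arms.items():
        drug = None
        if drug_name is not None:
            conc, actions = spec
            drug = get_drug(drug_name).at(conc, actions)
        res = run_strand(StrandConfig(condition=cond), drug=drug,
                         n_beats=4, n_prebeats=100)
        out[(cond, arm)] = dict(
            result=res,
            qt=measure_qt(res.pecg),
            cv=measure_cv(res.t, res.V, res.config),
        )
    return out


@pytest.fixture(scope="session")
def sqt1_endo_biomarkers():
    return paced_biomarkers(CellParams("ENDO", "SQT1"), n_prebeats=100)
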