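import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from renalpv.faers_io import RawQuarter
from renalpv.vocabulary import builtin_event_dictionary, builtin_ici_vocabulary


@pytest.fixture(scope="session")
def vocab():
    return builtin_ici_vocabulary()


@pytest.fixture(scope="session")
def renal_dict():
    return builtin_event_dictionary()


def make_quarter(demo_rows, drug_rows, reac_rows, outc_rows):
    """Hand-built RawQuarter from lists of dicts (missing columns blank)."""
    demo_cols = ["primaryid", "caseid", "caseversion", "fda_dt", "event_dt",
                 "age", "age_cod", "sex", "occr_country"]
    demo = pd.DataFrame(demo_rows, columns=demo_cols).fillna("").astype(str)
    drug = pd.DataFrame(drug_rows, columns=["primaryid", "drug_seq", "drugname", "role_cod"]).fillna("").astype(str)
    reac = pd.DataFrame(reac_rows, columns=["primaryid", "pt"]).fillna("").astype(str)
    outc = pd.DataFrame(outc_rows, columns=["primaryid", "outc_cod"]).fillna("").astype(str)
    return RawQuarter(demo=demo, drug=drug, reac=reac, outc=outc)


@pytest.fixture
def tiny_quarter():
    """Three reports: two-drug/three-PT, a case-version pair, one with death."""
    return make_quarter(
        demo_rows=[
            {"primaryid": "11", "caseid": "1", "caseversion": "1", "fda_dt": "20180301",
             "age": "63", "age_cod": "YR", "sex": "M", "event_dt": "20180110", "occr_country": "US"},
            {"primaryid": "21", "caseid": "2", "caseversion": "1", "fda_dt": "20180401",
             "age": "720", "age_cod": "MON", "sex": "F", "event_dt": "20180210", "occr_country": "JP"},
            {"primaryid": "22", "caseid": "2", "caseversion": "2", "fda_dt": "20180501",
             "age": "720", "age_cod": "MON", "sex": "F", "event_dt": "20180210", "occr_country": "JP"},
        ],
        drug_rows=[
            {"primaryid": "11", "drug_seq": "1", "drugname": "OPDIVO", "role_cod": "PS"},
            {"primaryid": "11", "drug_seq": "2", "drugname": "carboplatin", "role_cod": "SS"},
            {"primaryid": "21", "drug_seq": "1", "drugname": "KEYTRUDA", "role_cod": "PS"},
            {"primaryid": "22", "drug_seq": "1", "drugname": "KEYTRUDA", "role_cod": "PS"},
        ],
        reac_rows=[
            {"primaryid": "11", "pt": "Acute kidney injury"},
            {"primaryid": "11", "pt": "Nausea"},
            {"primaryid": "11", "pt": "Fatigue"},
            {"primaryid": "21", "pt": "Nephritis"},
            {"primaryid": "22", "pt": "Nephritis"},
        ],
        outc_rows=[
            {"primaryid": "11", "outc_cod": "DE"},
            {"primaryid": "11", "outc_cod": "HO"},
            {"primaryid": "22", "outc_cod": "HO"},
        ],
    )
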