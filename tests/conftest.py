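import textwrap

import pytest

from pvsignals import GeneratorConfig, deduplicate, generate_store
from pvsignals.datafiles import packaged_term_sets
from pvsignals.store import parse_quarter


@pytest.fixture(scope="session")
def term_sets():
    return packaged_term_sets()


@pytest.fixture(scope="session")
def small_synth():
    """A 2000-case quarter: 80-report pregnancy stratum, 5+3 decoys, one
    injected signal; returns (raw store, ground truth)."""
    cfg = GeneratorConfig(
        n_cases=2000,
        pregnancy_fraction=0.04,
        n_paternal_decoys=5,
        n_male_decoys=3,
        injected_signals={"PT_0020": 8.0},
        seed=7,
    )
    return generate_store(cfg)


@pytest.fixture(scope="session")
def small_dedup(small_synth):
    store, truth = small_synth
    return deduplicate(store), truth


def write_quarter_files(tmp_path, demo=None, drug=None, reac=None, indi=None,
                        ther=None, outc=None, deleted=None):
    """Write literal $-delimited quarter files and return the path mapping."""
    contents = {
        "demo": demo, "drug": drug, "reac": reac, "indi": indi,
        "ther": ther, "outc": outc, "deleted": deleted,
    }
    paths = {}
    for name, text in contents.items():
        if text is None:
            continue
        p = tmp_path / f"{name.upper()}25Q1.txt"
        p.write_text(textwrap.dedent(text).strip() + "\n")
        paths[name] = p
    return paths


@pytest.fixture()
def tiny_store(tmp_path):
    """Hand-written three-report quarter exercising all tables."""
    paths = write_quarter_files(
        tmp_path,
        demo="""
        primaryid$caseid$fda_dt$event_dt$sex$age$age_cod$occp_cod$occr_country
        101$A1$20200115$20200110$F$34$YR$MD$US
        102$A2$20210601$$M$$$CN$GB
        103$A3$20220301$202203$F$24$MON$PH$FR
        """,
        drug="""
        primaryid$drug_seq$role_cod$drugname
        101$1$PS$Lantus SoloStar
        101$2$C$METFORMIN
        102$1$PS$INSULIN GLARGINE
        103$1$SS$ASPIRIN
        """,
        reac="""
        primaryid$pt
        101$Hypoglycaemia
        101$Hypoglycaemia
        101$Headache
        102$Nausea
        103$Rash
        """,
        indi="""
        primaryid$indi_drug_seq$indi_pt
        101$1$DIABETES MELLITUS
        103$1$GESTATIONAL DIABETES
        """,
        ther="""
        primaryid$dsg_drug_seq$start_dt$end_dt
        101$1$20200101$20200301
        102$1$202105$
        """,
        outc="""
        primaryid$outc_cod
        101$HO
        102$OT
        """,
    )
    return parse_quarter(paths)
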