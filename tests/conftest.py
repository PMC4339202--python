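import math

import pandas as pd
import pytest

from lossmark import EvalueMatrix, TaxonPanel

INF = math.inf


@pytest.fixture(scope="session")
def panel() -> TaxonPanel:
    return TaxonPanel()


def make_matrix(panel: TaxonPanel, rows: dict, flags: dict | None = None,
                animal_hit_taxon: dict | None = None,
                reciprocal_family: dict | None = None) -> EvalueMatrix:
    """Build a small EvalueMatrix; unspecified taxa default to no-hit, and
    orthology flags default to 'present in Dikarya, absent in bilaterians'."""
    taxa = sorted(panel.all_taxa)
    flag_taxa = sorted(panel.dikarya | panel.bilateria_seed)
    ev = pd.DataFrame(
        {t: [rows[g].get(t, INF) for g in rows] for t in taxa}, index=list(rows)
    )
    default_flags = {}
    for g in rows:
        default_flags[g] = {t: "one2one" for t in panel.dikarya}
        default_flags[g].update({t: "none" for t in panel.bilateria_seed})
    if flags:
        for g, f in flags.items():
            default_flags[g].update(f)
    fl = pd.DataFrame(
        {t: [default_flags[g][t] for g in rows] for t in flag_taxa}, index=list(rows)
    )
    return EvalueMatrix(ev, fl, animal_hit_taxon=animal_hit_taxon or {},
                        reciprocal_family=reciprocal_family or {})


@pytest.fixture
def small_matrix(panel):
    """Five genes exercising each screen stage."""
    rows = {
        # passes everything: strong everywhere outside animals, no animal hit
        "lostA": {**{t: 1e-80 for t in panel.dikarya},
                  panel.choano_primary: 1e-90,
                  **{t: 1e-60 for t in panel.holozoa_secondary}},
        # fails stage 2: weak choanoflagellate match
        "weakChoano": {**{t: 1e-80 for t in panel.dikarya},
                       panel.choano_primary: 1e-20,
                       **{t: 1e-60 for t in panel.holozoa_secondary}},
        # fails stage 3: undetectable in one secondary holozoan
        "weakHolo": {**{t: 1e-80 for t in panel.dikarya},
                     panel.choano_primary: 1e-90,
                     "S_rosetta": 1e-60},
        # fails stage 4: animal match beats even the best non-animal holozoan
        "animalHit": {**{t: 1e-80 for t in panel.dikarya},
                      panel.choano_primary: 1e-90,
                      **{t: 1e-60 for t in panel.holozoa_secondary},
                      "T_adhaerens": 1e-95},
        # fails stage 1: present in human
        "retained": {t: 1e-80 for t in sorted(panel.all_taxa)},
    }
    flags = {"retained": {"H_sapiens": "one2one", "D_melanogaster": "one2one"}}
    return make_matrix(panel, rows, flags)
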