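"""Reference tables for the Finnish NCD risk-factor survey series.

The Finnish national risk-factor monitoring programme ran five
cross-sectional health examination surveys between 1997 and 2017 (every
five years, ages 25-64, five study areas).  The person-level microdata
are not publicly deposited, but the published summary tables -- sample
sizes, response rates, and observed/projected prevalence changes -- are.
Those summaries are embedded here: they calibrate the synthetic-data
generator and serve as worked-example inputs for the reporting module.
"""

from __future__ import annotations

import io

import pandas as pd

MEN = 0
WOMEN = 1
SEX_LABELS = {MEN: "men", WOMEN: "women"}

WAVE_YEARS = (1997, 2002, 2007, 2012, 2017)

#: Original (invited) sample sizes per survey wave.
INVITED_N = {
    MEN: {1997: 5000, 2002: 4999, 2007: 4000, 2012: 4000, 2017: 1635},
    WOMEN: {1997: 5000, 2002: 5000, 2007: 4000, 2012: 4000, 2017: 1542},
}

#: Response rate to the survey questionnaire (%), by sex and wave.
QUESTIONNAIRE_RESPONSE_PCT = {
    MEN: {1997: 67.9, 2002: 65.0, 2007: 60.3, 2012: 56.9, 2017: 60.6},
    WOMEN: {1997: 72.3, 2002: 75.3, 2007: 70.5, 2012: 66.5, 2017: 70.0},
}

#: Participation rate in the health examination (%), by sex and wave.
EXAMINATION_PARTICIPATION_PCT = {
    MEN: {1997: 67.9, 2002: 58.8, 2007: 56.1, 2012: 51.5, 2017: 51.9},
    WOMEN: {1997: 72.3, 2002: 69.8, 2007: 65.6, 2012: 59.7, 2017: 61.9},
}

INDICATORS = (
    "smoking",
    "sedentary",
    "hypertension",
    "elevated_tc",
    "overweight",
    "obesity",
    "diabetes",
)

#: Observed prevalence (%) in 2017 and observed change (percentage points)
#: from 1997, as published for the survey series.
_OBSERVED_CSV = """\
indicator,sex,prev_2017_pct,abs_change_1997_2017_pp,rel_change_1997_2017_pct
smoking,men,22.6,-9.6,-29.7
smoking,women,16.9,-3.2,-15.8
sedentary,men,23.9,1.6,7.3
sedentary,women,25.3,1.8,7.6
hypertension,men,41.9,-7.2,-14.7
hypertension,women,26.8,-6.9,-20.4
elevated_tc,men,59.4,-9.1,-13.3
elevated_tc,women,53.4,-10.2,-16.0
obesity,men,23.7,5.3,29.0
obesity,women,21.1,2.4,12.6
overweight,men,42.5,-4.7,-10.0
overweight,women,30.0,-1.9,-5.9
diabetes,men,6.8,4.3,170.6
diabetes,women,3.6,2.4,196.4
"""

#: Projected changes from the 2017 baseline (percentage points / %),
#: as published for the survey series.
_PROJECTED_CSV = """\
indicator,sex,year,abs_change_pp,rel_change_pct
smoking,men,2025,-6.3,-27.7
smoking,men,2030,-9.2,-40.7
smoking,men,2040,-13.8,-61.2
smoking,women,2025,-3.6,-21.3
smoking,women,2030,-5.3,-31.6
smoking,women,2040,-8.3,-49.3
sedentary,men,2025,-0.7,-3.0
sedentary,men,2030,-0.4,-1.6
sedentary,men,2040,0.7,3.0
sedentary,women,2025,-1.0,-4.1
sedentary,women,2030,-0.6,-2.4
sedentary,women,2040,0.5,2.0
hypertension,men,2025,-1.5,-3.6
hypertension,men,2030,-2.8,-6.8
hypertension,men,2040,-3.7,-8.9
hypertension,women,2025,0.9,3.5
hypertension,women,2030,-0.1,-0.3
hypertension,women,2040,-0.9,-3.3
elevated_tc,men,2025,-7.05,-11.9
elevated_tc,men,2030,-10.40,-17.5
elevated_tc,men,2040,-16.29,-27.4
elevated_tc,women,2025,-6.23,-11.6
elevated_tc,women,2030,-9.30,-17.4
elevated_tc,women,2040,-14.57,-27.2
obesity,men,2025,0.5,2.3
obesity,men,2030,1.9,8.0
obesity,men,2040,5.4,22.8
obesity,women,2025,2.4,11.5
obesity,women,2030,3.3,15.7
obesity,women,2040,6.4,30.3
overweight,men,2025,-2.1,-4.8
overweight,men,2030,-3.4,-8.0
overweight,men,2040,-6.3,-14.3
overweight,women,2025,-2.9,-9.5
overweight,women,2030,-3.9,-13.1
overweight,women,2040,-6.0,-19.9
diabetes,men,2025,3.5,51.1
diabetes,men,2030,5.9,87.6
diabetes,men,2040,13.2,194.2
diabetes,women,2025,2.6,73.9
diabetes,women,2030,4.2,119.7
diabetes,women,2040,9.5,266.6
"""


def observed_changes() -> pd.DataFrame:
    """Published 2017 prevalences and 1997->2017 changes, one row per
    indicator x sex."""
    return pd.read_csv(io.StringIO(_OBSERVED_CSV))


def projected_changes() -> pd.DataFrame:
    """Published projected changes from 2017, one row per
    indicator x sex x projection year."""
    return pd.read_csv(io.StringIO(_PROJECTED_CSV))


def endpoint_prevalence() -> pd.DataFrame:
    """Prevalence (proportions) at the first and last observed waves.

    The 1997 value is reconstructed as the 2017 prevalence minus the
    observed absolute change.  These two endpoints are what the
    synthetic-data generator's default logit-linear trends are
    calibrated against.
    """
    obs = observed_changes()
    out = obs[["indicator", "sex"]].copy()
    out["p_1997"] = (obs["prev_2017_pct"] - obs["abs_change_1997_2017_pp"]) / 100.0
    out["p_2017"] = obs["prev_2017_pct"] / 100.0
    return out
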