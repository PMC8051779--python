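"""Published okra-extraction study tables, as programmatic fixtures.

Everything here is transcribed from the printed tables of the source
study on aqueous polyphenol extraction from *Abelmoschus esculentus*
(okra) fruits: the factor levels, the 20-run blocked CCRD with its
measured total polyphenol content (TPC), the fitted coded-unit model
coefficients, the reference ANOVA, the HPLC peak table, and the in-vivo
fasting-plasma-glucose / body-weight group summaries.

Transcription notes
-------------------
* The run sheet prints the label "3" twice and no run "2"; rows are
  treated positionally (20 rows = 20 runs) and ``run`` below is simply
  the row number.
* The axial actuals are printed rounded (77 for 76.82 degC, 43 for
  43.18 degC), so coding them back gives +/-1.70 rather than +/-1.68179;
  points are classified by pattern, not by exact axial distance.
* The six centre responses give a within-block pure-error SS of ~3.09
  (pooled: ~6.09), not the 12.31 the reference ANOVA prints; refitting
  the run sheet likewise does not reproduce the published coefficients
  exactly. The printed tables are kept verbatim and the discrepancy is
  documented rather than "corrected".
"""

from __future__ import annotations

from io import StringIO

import numpy as np
import pandas as pd

from .design import Factor, design_from_actuals
from .rsm import ResponseData

# -- factor definitions (time h, temperature degC, solid-to-solvent ratio % w/v)

def extraction_factors() -> list[Factor]:
    """The three extraction factors with their -1/+1 actual levels."""
    return [
        Factor("time", "h", 1.0, 2.0),
        Factor("temperature", "degC", 50.0, 70.0),
        Factor("ratio", "% w/v", 2.5, 5.0),
    ]


_CCRD_RUNS_CSV = """\
run,block,time_h,temperature_C,ratio_pct,tpc_mg_gae_per_g
1,1,1,50,5,14.54
2,1,1.5,60,3.75,16.60
3,1,1.5,60,3.75,15.90
4,1,1.5,60,3.75,15.96
5,1,1,50,2.5,13.20
6,1,2,70,5,19.21
7,1,2,70,2.5,21.29
8,1,1.5,60,3.75,16.10
9,1,1,70,5,17.25
10,1,2,50,2.5,12.46
11,1,2,50,5,10.54
12,1,1,70,2.5,18.00
13,2,0.66,60,3.75,16.67
14,2,1.5,60,1.65,10.08
15,2,1.5,60,5.85,15.25
16,2,1.5,60,3.75,13.46
17,2,1.5,76.82,3.75,17.29
18,2,1.5,43.18,3.75,12.10
19,2,2.34,60,3.75,14.63
20,2,1.5,60,3.75,15.82
"""


def ccrd_runs() -> pd.DataFrame:
    """The 20-run blocked CCRD with measured TPC (mg GAE/g DW).

    The axial temperatures are restored to their exact values (76.82 /
    43.18 degC; the run sheet prints them rounded to 77 / 43).
    """
    return pd.read_csv(StringIO(_CCRD_RUNS_CSV))


def tpc_response_data() -> ResponseData:
    """The run sheet packaged as ResponseData ready for model fitting."""
    runs = ccrd_runs()
    factors = extraction_factors()
    design = design_from_actuals(
        factors,
        runs[["time_h", "temperature_C", "ratio_pct"]].to_numpy(),
        runs["block"],
    )
    return ResponseData(
        design=design,
        response=runs["tpc_mg_gae_per_g"].to_numpy(),
        response_name="tpc_mg_gae_per_g",
    )


def fitted_tpc_coefficients() -> dict[str, float]:
    """The published coded-unit quadratic model for TPC (mg GAE/g DW).

    Keys follow the usual design-of-experiments letter convention:
    A = time, B = temperature, C = ratio.
    """
    return {
        "Intercept": 14.75,
        "A": -0.3063,
        "B": 2.02,
        "C": 1.67,
        "AB": -2.06,
        "AC": -3.39,
        "BC": 0.1250,
        "A^2": 0.7191,
        "B^2": -2.01,
        "C^2": -0.8645,
    }


_ANOVA_CSV = """\
source,ss,df,ms,f,p
block,24.49,1,24.49,,
model,299.84,9,33.32,4.74,0.0079
A,1.28,1,1.28,0.2207,0.6496
B,55.69,1,55.69,9.59,0.0128
C,38.12,1,38.12,6.57,0.0306
AB,34.03,1,34.03,5.86,0.0385
AC,91.69,1,91.69,15.79,0.0032
BC,0.1250,1,0.1250,0.0215,0.8866
A^2,7.45,1,7.45,1.28,0.2867
B^2,58.39,1,58.39,10.76,0.0113
C^2,10.76,1,10.76,1.85,0.2064
residual,52.25,9,5.81,,
lack_of_fit,39.94,5,7.99,2.60,0.1882
pure_error,12.31,4,3.08,,
corrected_total,376.58,19,,,
"""


def reference_anova() -> pd.DataFrame:
    """The published ANOVA for the quadratic TPC model, verbatim."""
    return pd.read_csv(StringIO(_ANOVA_CSV))


_HPLC_PEAKS_CSV = """\
id,rt_min,area,height
1,3.794,201032,11196
2,3.963,182217,17960
3,4.164,293826,27584
4,4.544,829269,37788
5,4.968,657958,25133
6,5.523,182944,14381
7,6.059,30332,1880
8,6.467,74535,2830
9,7.497,1274,132
10,8.066,213665,7665
11,19.81,5744,137
12,23.544,2731,90
13,49.665,1118,41
"""


def hplc_peaks() -> pd.DataFrame:
    """The 13 integrated HPLC fingerprint peaks of the okra extract.

    Peak 1's height is restored to 11196: the printed 1196 is missing a
    digit — the published percent-height column (7.626% of the printed
    total 146818) and the total itself are only consistent with 11196
    (the 13 printed heights otherwise sum to 136817, not 146818).
    """
    return pd.read_csv(StringIO(_HPLC_PEAKS_CSV))


# In-vivo summaries: n = 6 rats per group; values are mean +/- SEM.
# Groups: normal control, diabetic control (both dosed distilled water),
# extract at 100 and 200 mg/kg, glibenclamide 5 mg/kg.
_FPG_CSV = """\
group,dose_mg_per_kg,timepoint_day,n,mean,sem,units
normal_control,,1,6,5.5,0.34,mmol/L
normal_control,,7,6,5.5,0.23,mmol/L
normal_control,,14,6,6.2,0.33,mmol/L
diabetic_control,,1,6,11.1,0.87,mmol/L
diabetic_control,,7,6,16.1,0.90,mmol/L
diabetic_control,,14,6,18.1,1.21,mmol/L
aefe_100,100,1,6,10.6,1.04,mmol/L
aefe_100,100,7,6,7.8,0.50,mmol/L
aefe_100,100,14,6,6.5,0.15,mmol/L
aefe_200,200,1,6,12.6,1.02,mmol/L
aefe_200,200,7,6,7.9,0.35,mmol/L
aefe_200,200,14,6,6.0,0.23,mmol/L
glibenclamide_5,5,1,6,10.7,0.79,mmol/L
glibenclamide_5,5,7,6,8.0,0.39,mmol/L
glibenclamide_5,5,14,6,6.4,0.25,mmol/L
"""

_WEIGHT_CSV = """\
group,dose_mg_per_kg,timepoint_day,n,mean,sem,units
normal_control,,1,6,261,10.22,g
normal_control,,7,6,262,10.46,g
normal_control,,14,6,262,10.46,g
diabetic_control,,1,6,273,7.44,g
diabetic_control,,7,6,269,17.34,g
diabetic_control,,14,6,268,15.35,g
aefe_100,100,1,6,273,11.65,g
aefe_100,100,7,6,281,13.68,g
aefe_100,100,14,6,290,14.09,g
aefe_200,200,1,6,268,7.14,g
aefe_200,200,7,6,269,6.25,g
aefe_200,200,14,6,274,7.93,g
glibenclamide_5,5,1,6,237,17.77,g
glibenclamide_5,5,7,6,251,15.82,g
glibenclamide_5,5,14,6,265,15.71,g
"""


def fpg_summaries() -> pd.DataFrame:
    """Fasting-plasma-glucose group summaries (mmol/L) at days 1, 7, 14."""
    return pd.read_csv(StringIO(_FPG_CSV))


def weight_summaries() -> pd.DataFrame:
    """Body-weight group summaries (g) at days 1, 7, 14."""
    return pd.read_csv(StringIO(_WEIGHT_CSV))


def single_factor_peaks() -> dict[str, tuple[float, float]]:
    """Peak (location, yield) anchors from the single-factor screens:
    TPC peaked at 17.4 mg GAE/g DW at 70 degC, 18 at 2 h, and 17.7 at a
    2.5% solid-to-solvent ratio."""
    return {
        "temperature": (70.0, 17.4),
        "time": (2.0, 18.0),
        "ratio": (2.5, 17.7),
    }


def residual_noise_sd() -> float:
    """Residual SD implied by the published ANOVA (MS_resid = 5.81)."""
    return float(np.sqrt(5.81))
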