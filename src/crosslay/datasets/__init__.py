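"""Bundled worked-example data.

``load_predicted_group_means`` returns the published predicted group means
(and printed heterosis / reciprocal-difference percentages with their FDR
significance markers) for 70 egg-laying traits of a reciprocal-cross
experiment between White Leghorn (W) and Beijing-You (Y) layer lines:
egg weights from the first eggs to 100 weeks of age, egg-production traits
at 43/72/100 weeks, and egg-quality traits at five ages.  Group labels put
the sire line first (WY = W sire x Y dam).
"""

from importlib import resources

import pandas as pd

__all__ = ["load_predicted_group_means"]


def load_predicted_group_means() -> pd.DataFrame:
    with resources.files(__package__).joinpath("predicted_group_means.csv").open() as fh:
        df = pd.read_csv(fh, keep_default_na=False)
    for col in ("WW", "YY", "WY", "YW", "H_pct_WY_printed", "H_pct_YW_printed",
                "recip_pct_printed"):
        df[col] = pd.to_numeric(df[col])
    return df.set_index("trait")
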