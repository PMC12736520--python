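"""Bundled reference tables for the genus *Chloroidium*.

Two small published summaries travel with the package so that the
worked examples and regression checks run without external downloads:

* per-barcode intra/interspecific K2P distance ranges (percent units);
* the fatty-acid composition (mean +/- SD mass%, n = 3) of strain
  VKM Al-418 grown at 9, 22, and 27 degrees C.
"""

from importlib.resources import files

import pandas as pd

FA_REPLICATES_N = 3  # biological replicates behind the published means/SDs


def load_barcode_ranges() -> pd.DataFrame:
    """Published intra/inter distance ranges per DNA barcode (percent)."""
    path = files(__package__).joinpath("chloroidium_barcode_ranges.tsv")
    return pd.read_csv(path, sep="\t", index_col="marker")


def load_fa_profiles() -> pd.DataFrame:
    """Published FA means/SDs (mass% of total) at three growth temperatures.

    Undetected fatty acids carry mean 0, SD 0.
    """
    path = files(__package__).joinpath("chloroidium_vkm_al418_fa.tsv")
    return pd.read_csv(path, sep="\t", index_col="fa")
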