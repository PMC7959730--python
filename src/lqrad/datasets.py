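"""Published reference LQ parameters for nasopharyngeal carcinoma models.

Published point estimates of the LQ parameters for patient-derived NPC
organoids, C666-1 spheroids and C666-1 monolayers assayed at days 14 and 21
under normoxia (21% O2) and physiological hypoxia (1% O2). The alpha/beta
column carries the ratio as printed in the source study, computed there from
unrounded estimates; dividing the rounded alpha by the rounded beta
reproduces it only to about 2%.

These values parameterize the default synthetic experiments and the
worked examples; the raw survival curves behind them were not published.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["load_npc_lq_parameters", "organoid_parameters"]

_ROWS = [
    # condition, day, system, alpha, se_alpha, beta, se_beta, ab_printed, gof
    ("normoxic_21pct", 14, "organoid", 0.0131, 0.0057, 0.0014, 0.0002, 9.3494, 0.9869),
    ("normoxic_21pct", 14, "spheroid", 0.0206, 0.0095, 0.0033, 0.0008, 6.1500, 0.9820),
    ("normoxic_21pct", 14, "monolayer", 0.0552, 0.0258, 0.0064, 0.0020, 8.6202, 0.9886),
    ("normoxic_21pct", 21, "organoid", 0.0873, 0.0105, 0.0054, 0.0012, 16.2259, 0.9991),
    ("normoxic_21pct", 21, "spheroid", 0.0368, 0.0093, 0.0061, 0.0007, 6.0730, 0.9960),
    ("normoxic_21pct", 21, "monolayer", 0.0956, 0.0349, 0.0087, 0.0041, 10.9675, 0.9850),
    ("hypoxic_1pct", 14, "organoid", 0.0460, 0.0090, 0.0029, 0.0010, 15.6889, 0.9974),
    ("hypoxic_1pct", 14, "spheroid", 0.0349, 0.0201, 0.0030, 0.0016, 11.7556, 0.9681),
    ("hypoxic_1pct", 14, "monolayer", 0.0216, 0.0098, 0.0017, 0.0004, 12.5394, 0.9791),
    ("hypoxic_1pct", 21, "organoid", 0.0254, 0.0097, 0.0013, 0.0004, 19.6918, 0.9740),
    ("hypoxic_1pct", 21, "spheroid", 0.0615, 0.0190, 0.0021, 0.0011, 29.3534, 0.9880),
    ("hypoxic_1pct", 21, "monolayer", 0.0323, 0.0184, 0.0042, 0.0015, 7.7581, 0.9725),
]


def load_npc_lq_parameters() -> pd.DataFrame:
    """The full 12-row published NPC LQ parameter table as a DataFrame."""
    return pd.DataFrame(
        _ROWS,
        columns=[
            "oxygen_condition",
            "assay_day",
            "model_system",
            "alpha",
            "se_alpha",
            "beta",
            "se_beta",
            "alpha_beta_printed",
            "goodness_of_fit",
        ],
    )


def organoid_parameters() -> pd.DataFrame:
    """The four organoid rows (both conditions x days 14/21)."""
    df = load_npc_lq_parameters()
    return df[df["model_system"] == "organoid"].reset_index(drop=True)
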