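"""Published summary statistics for the 30-locus DIPplex InDel panel in a
Polish population sample (n = 631).

These are the printed per-locus values from the population study this
package re-analyses: deletion/insertion allele frequencies, the two
heterozygosity columns, the HWE p-value, and the forensic efficiency
parameters PIC, PD, PE and TPI.  They serve as the reference inputs for
genotype-count reconstruction and as frozen expected values for the
panel-level computations.

Column convention
-----------------
As printed, the column labelled "Ho" actually holds Nei's *unbiased expected*
heterozygosity (it equals ``2pq * 2n/(2n-1)`` from the printed allele
frequencies at every locus, to rounding) and the column labelled "He" holds
the *observed* heterozygote proportion (it contains 0.5436, which exceeds the
biallelic expected-heterozygosity ceiling of ~0.5004 at n = 631).  The loader
verifies this numerically and :func:`check_heterozygosity_columns` reports
the per-locus residuals, so ``het_exp`` below maps to the printed "Ho" column
and ``het_obs`` to the printed "He" column.
"""

from __future__ import annotations

import pandas as pd

from .types import Locus, ValidationError

#: Number of individuals genotyped in the published sample.
PANEL_N = 631

# id, location, rs_id, p_del, p_ins, het_exp ("Ho" col), het_obs ("He" col),
# p_hwe, pic, pd, pe, tpi
_PANEL_ROWS = [
    ("HLD77", "7q31.1", "rs1611048", 0.4422, 0.5578, 0.4937, 0.4628, 0.1224, 0.3716, 0.6348, 0.1569, 0.9307),
    ("HLD45", "2q31.1", "rs2307959", 0.4739, 0.5261, 0.4990, 0.5040, 0.8096, 0.3743, 0.6216, 0.1910, 1.0080),
    ("HLD131", "7q36.2", "rs1611001", 0.4564, 0.5436, 0.4966, 0.4628, 0.0934, 0.3731, 0.6377, 0.1569, 0.9307),
    ("HLD70", "6q16.1", "rs2307652", 0.4731, 0.5269, 0.4989, 0.4929, 0.8100, 0.3743, 0.6270, 0.1813, 0.9859),
    ("HLD6", "16q13", "rs1610905", 0.4707, 0.5293, 0.4987, 0.4564, 0.0384, 0.3741, 0.6422, 0.1521, 0.9198),
    ("HLD111", "17p11.2", "rs1305047", 0.4976, 0.5024, 0.5004, 0.4818, 0.3837, 0.3750, 0.6336, 0.1720, 0.9648),
    ("HLD58", "5q14.1", "rs1610937", 0.4461, 0.5539, 0.4946, 0.4739, 0.2955, 0.3721, 0.6312, 0.1656, 0.9503),
    ("HLD56", "4q25", "rs2308292", 0.3352, 0.6648, 0.4460, 0.4358, 0.5868, 0.3464, 0.5966, 0.1372, 0.8862),
    ("HLD118", "20p11.1", "rs16438", 0.5143, 0.4857, 0.5000, 0.4707, 0.1451, 0.3748, 0.6380, 0.1631, 0.9446),
    ("HLD92", "11q22.2", "rs17174476", 0.5919, 0.4081, 0.4835, 0.4707, 0.5146, 0.3664, 0.6215, 0.1631, 0.9446),
    ("HLD93", "12q22", "rs2307570", 0.4477, 0.5523, 0.4949, 0.5436, 0.0157, 0.3722, 0.5949, 0.2286, 1.0955),
    ("HLD99", "14q23.1", "rs2308163", 0.4097, 0.5903, 0.4841, 0.4929, 0.6853, 0.3667, 0.6122, 0.1813, 0.9859),
    ("HLD88", "9q22.32", "rs8190570", 0.5895, 0.4105, 0.4843, 0.4881, 0.8711, 0.3669, 0.6147, 0.1773, 0.9768),
    ("HLD101", "15q26.1", "rs2307433", 0.4786, 0.5214, 0.4995, 0.4913, 0.7021, 0.3745, 0.6283, 0.1800, 0.9829),
    ("HLD67", "5q33.2", "rs1305056", 0.3954, 0.6046, 0.4785, 0.4834, 0.8013, 0.3638, 0.6110, 0.1734, 0.9678),
    ("HLD83", "8p22", "rs2308072", 0.5127, 0.4873, 0.5001, 0.5119, 0.5797, 0.3748, 0.6185, 0.1981, 1.0244),
    ("HLD114", "17p13.3", "rs2307581", 0.6513, 0.3487, 0.4545, 0.4469, 0.7246, 0.3510, 0.6015, 0.1451, 0.9040),
    ("HLD48", "2q11.2", "rs28369942", 0.4770, 0.5230, 0.4993, 0.4628, 0.0669, 0.3745, 0.6405, 0.1569, 0.9307),
    ("HLD124", "22q12.3", "rs6481", 0.3574, 0.6426, 0.4597, 0.4612, 1.0000, 0.3538, 0.6015, 0.1557, 0.9279),
    ("HLD122", "21q22.11", "rs8178524", 0.5388, 0.4612, 0.4974, 0.5261, 0.1444, 0.3735, 0.6079, 0.2114, 1.0552),
    ("HLD125", "22q11.23", "rs16388", 0.4889, 0.5111, 0.5002, 0.4897, 0.6298, 0.3749, 0.6297, 0.1786, 0.9798),
    ("HLD64", "5q12.3", "rs1610935", 0.4532, 0.5468, 0.4960, 0.4501, 0.0258, 0.3728, 0.6419, 0.1474, 0.9092),
    ("HLD81", "7q21.3", "rs17879936", 0.5689, 0.4311, 0.4909, 0.4437, 0.0184, 0.3702, 0.6389, 0.1428, 0.8989),
    ("HLD136", "22q13.1", "rs16363", 0.5475, 0.4525, 0.4959, 0.4834, 0.5776, 0.3727, 0.6284, 0.1734, 0.9678),
    ("HLD133", "3p22.1", "rs2067235", 0.4461, 0.5539, 0.4946, 0.4739, 0.2933, 0.3721, 0.6312, 0.1656, 0.9503),
    ("HLD97", "13q12.3", "rs17238892", 0.4493, 0.5507, 0.4952, 0.4834, 0.5686, 0.3724, 0.6278, 0.1734, 0.9678),
    ("HLD40", "1p32.3", "rs2307956", 0.5634, 0.4366, 0.4924, 0.4580, 0.0871, 0.3709, 0.6353, 0.1533, 0.9225),
    ("HLD128", "1q31.3", "rs2307924", 0.5563, 0.4437, 0.4941, 0.4691, 0.2199, 0.3718, 0.6327, 0.1619, 0.9418),
    ("HLD39", "1p22.1", "rs17878444", 0.6268, 0.3732, 0.4682, 0.4263, 0.0265, 0.3584, 0.6216, 0.1307, 0.8715),
    ("HLD84", "8q24.12", "rs3081400", 0.4532, 0.5468, 0.4960, 0.4945, 1.0000, 0.3728, 0.6234, 0.1827, 0.9890),
]

_COLUMNS = [
    "locus", "location", "rs_id", "p_del", "p_ins",
    "het_exp", "het_obs", "p_hwe", "pic", "pd", "pe", "tpi",
]


def polish_panel_frame() -> pd.DataFrame:
    """The published per-locus summary as a DataFrame (one row per locus).

    ``het_exp`` / ``het_obs`` follow the numerically verified convention
    described in the module docstring, not the printed column labels.
    """
    df = pd.DataFrame(_PANEL_ROWS, columns=_COLUMNS)
    _verify_column_convention(df)
    return df


def polish_panel_loci() -> list[Locus]:
    return [
        Locus(id=r[0], location=r[1], rs_id=r[2], alleles=("D", "I"))
        for r in _PANEL_ROWS
    ]


def check_heterozygosity_columns(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-locus residuals of the two heterozygosity columns against the
    unbiased expected heterozygosity implied by the printed allele frequencies.

    Returns a frame with columns ``resid_het_exp`` (printed "Ho" column minus
    ``2pq * 2n/(2n-1)``) and ``resid_if_swapped`` (printed "He" column minus
    the same quantity).  Under the verified convention the former is within
    printed rounding (|resid| <= 1e-4) at every locus while the latter is not.
    """
    if df is None:
        df = pd.DataFrame(_PANEL_ROWS, columns=_COLUMNS)
    n = PANEL_N
    expected = (2 * n / (2 * n - 1)) * (1 - df["p_del"] ** 2 - df["p_ins"] ** 2)
    return pd.DataFrame(
        {
            "locus": df["locus"],
            "resid_het_exp": df["het_exp"] - expected,
            "resid_if_swapped": df["het_obs"] - expected,
        }
    )


def _verify_column_convention(df: pd.DataFrame) -> None:
    resid = check_heterozygosity_columns(df)
    if (resid["resid_het_exp"].abs() > 1.0e-4).any():
        bad = resid.loc[resid["resid_het_exp"].abs() > 1.0e-4, "locus"].tolist()
        raise ValidationError(
            "heterozygosity column convention check failed at "
            f"{bad}: the 'het_exp' column does not equal the unbiased "
            "expected heterozygosity implied by the allele frequencies"
        )
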