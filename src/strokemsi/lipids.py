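"""Monoisotopic adduct m/z calculation and peak annotation against a lipid table.

Ion masses of MALDI pseudo-molecular ions are computed from elemental
formulas using monoisotopic atomic masses (CODATA/IUPAC), with the electron
mass handled explicitly so that cation and anion adducts are exact:

    [M+H]+  = M + m(H) - m(e)
    [M+Na]+ = M + m(Na) - m(e)
    [M+K]+  = M + m(K) - m(e)
    [M-H]-  = M - m(H) + m(e)
    [M]+    = M - m(e)          (pre-charged fragments, e.g. choline C5H12N+)

Lipid shorthand such as ``PC(32:0)`` is resolved through a bundled TSV table
mapping shorthand to formula; no nomenclature parsing is attempted.
"""

from __future__ import annotations

import importlib.resources
import re

import numpy as np
import pandas as pd

# Monoisotopic atomic masses, Da.
MONOISOTOPIC_MASS = {
    "C": 12.000000,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "Na": 22.98976928,
    "K": 38.9637064864,
    "S": 31.97207069,
}

ELECTRON_MASS = 0.00054858
#: mass added by protonation (H minus one electron)
PROTON_MASS = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS

#: adduct tag -> (mass delta, charge)
ADDUCTS = {
    "+H": (PROTON_MASS, +1),
    "+Na": (MONOISOTOPIC_MASS["Na"] - ELECTRON_MASS, +1),
    "+K": (MONOISOTOPIC_MASS["K"] - ELECTRON_MASS, +1),
    "-H": (-PROTON_MASS, -1),
    "M+": (-ELECTRON_MASS, +1),
}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str | dict) -> dict:
    """Parse ``C40H80NO8P`` into an element->count dict."""
    if isinstance(formula, dict):
        counts = dict(formula)
    else:
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_RE.finditer(formula):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r}")
            pos = m.end()
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        if pos != len(formula):
            raise ValueError(f"cannot parse formula {formula!r}")
    for el, n in counts.items():
        if el not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element {el!r}")
        if n <= 0 or n != int(n):
            raise ValueError(f"element count for {el} must be a positive integer")
    return counts


def monoisotopic_mass(formula: str | dict) -> float:
    """Neutral monoisotopic mass (Da) of an elemental formula."""
    counts = parse_formula(formula)
    return float(sum(MONOISOTOPIC_MASS[el] * n for el, n in counts.items()))


def adduct_mz(formula: str | dict, adduct: str) -> float:
    """m/z of a singly charged adduct ion of ``formula``.

    ``adduct`` is one of ``+H``, ``+Na``, ``+K``, ``-H``, or ``M+`` (loss of
    one electron from a pre-charged species).
    """
    if adduct not in ADDUCTS:
        raise ValueError(f"unknown adduct {adduct!r}; expected one of {sorted(ADDUCTS)}")
    delta, _charge = ADDUCTS[adduct]
    mz = monoisotopic_mass(formula) + delta
    if mz <= 0:
        raise ValueError(f"non-physical m/z {mz} for {formula} {adduct}")
    return mz


def adduct_polarity(adduct: str) -> str:
    return "positive" if ADDUCTS[adduct][1] > 0 else "negative"


def load_lipid_table(path=None) -> pd.DataFrame:
    """Load a lipid table TSV (columns: name, formula, adducts, polarity).

    With no path, the bundled table of the PC/LPC/PI/PIP species relevant to
    ischemic brain tissue is returned.
    """
    if path is None:
        ref = importlib.resources.files("strokemsi") / "data" / "lipids.tsv"
        with importlib.resources.as_file(ref) as p:
            table = pd.read_csv(p, sep="\t", comment="#")
    else:
        table = pd.read_csv(path, sep="\t", comment="#")
    required = {"name", "formula", "adducts", "polarity"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"lipid table missing columns: {sorted(missing)}")
    return table


def table_ions(table: pd.DataFrame, polarity: str | None = None) -> pd.DataFrame:
    """Expand a lipid table into one row per (species, adduct) with computed m/z."""
    rows = []
    for rec in table.itertuples(index=False):
        for adduct in str(rec.adducts).split(","):
            adduct = adduct.strip()
            if polarity is not None and adduct_polarity(adduct) != polarity:
                continue
            rows.append(
                {
                    "name": rec.name,
                    "formula": rec.formula,
                    "adduct": adduct,
                    "mz": adduct_mz(rec.formula, adduct),
                }
            )
    return pd.DataFrame(rows, columns=["name", "formula", "adduct", "mz"])


def annotate_peaks(peaks, table: pd.DataFrame, tolerance: float = 0.3) -> pd.DataFrame:
    """Match peak windows against computed lipid-adduct m/z values.

    Every (species, adduct) whose computed m/z lies within ``tolerance`` Da of
    a peak center is reported; ties are listed nearest-first.

    Parameters
    ----------
    peaks : iterable of PeakWindow or float
        Peak centers (Da).
    table : DataFrame
        Lipid table as from :func:`load_lipid_table`.
    tolerance : float
        Match tolerance in Da (default 0.3, the peak-window half width).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    if len(table) == 0:
        raise ValueError("empty lipid table")
    ions = table_ions(table)
    centers = [float(getattr(p, "center", p)) for p in peaks]
    rows = []
    for center in centers:
        delta = np.abs(ions["mz"].to_numpy() - center)
        hits = np.flatnonzero(delta <= tolerance)
        for j in hits[np.argsort(delta[hits], kind="stable")]:
            rows.append(
                {
                    "peak_mz": center,
                    "name": ions.at[j, "name"],
                    "adduct": ions.at[j, "adduct"],
                    "ion_mz": ions.at[j, "mz"],
                    "delta_mz": float(ions.at[j, "mz"] - center),
                }
            )
    return pd.DataFrame(rows, columns=["peak_mz", "name", "adduct", "ion_mz", "delta_mz"])
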