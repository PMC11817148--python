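"""Element van der Waals parameter table.

Radii (Å) and well depths (kcal/mol) for the elements that occur in
drug-like ligands.  Shipped as a packaged CSV so the table is editable
without touching code; unknown elements raise rather than defaulting
silently.
"""

from __future__ import annotations

import functools
from importlib import resources

import pandas as pd


class UnknownElementError(KeyError):
    """Raised when an element has no entry in the vdW parameter table."""


@functools.lru_cache(maxsize=1)
def vdw_table() -> pd.DataFrame:
    """The packaged element parameter table, indexed by element symbol."""
    with resources.files("fieldqsar.data").joinpath("vdw_params.csv").open() as fh:
        df = pd.read_csv(fh)
    return df.set_index("element")


def vdw_params(element: str) -> tuple[float, float]:
    """Return ``(radius_Å, epsilon_kcal_mol)`` for *element*.

    Raises
    ------
    UnknownElementError
        If the element is not in the packaged table.
    """
    table = vdw_table()
    symbol = element.capitalize() if len(element) <= 2 else element
    if symbol not in table.index:
        raise UnknownElementError(f"no vdW parameters for element {element!r}")
    row = table.loc[symbol]
    return float(row["vdw_radius"]), float(row["vdw_epsilon"])
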