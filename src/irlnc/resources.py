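"""Access to the small text resources shipped with the package."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from . import io

_DATA = resources.files("irlnc") / "data"


def data_path(name: str) -> Path:
    path = Path(str(_DATA / name))
    if not path.exists():
        raise FileNotFoundError(f"no packaged resource named {name!r}")
    return path


def load_immune_sets() -> io.GeneSetCollection:
    """The packaged 17-category ImmPort-style immune gene-set collection."""
    return io.read_gmt(data_path("immune_categories.gmt"))


def load_cell_markers() -> io.GeneSetCollection:
    """Marker gene sets for the 10 default immune/stromal cell populations.

    These are gene-symbol stand-ins for the original microarray probe sets of
    the cell-population counter; they are configurable via any GMT file.
    """
    return io.read_gmt(data_path("cell_markers.gmt"))


def load_design(dataset: str) -> pd.DataFrame:
    """Packaged cohort design tables: ``"GSE92681"`` (5 normal / 7 pulpitis)
    or ``"GSE77459"`` (6 normal / 6 pulpitis)."""
    key = dataset.lower()
    if key not in {"gse92681", "gse77459"}:
        raise KeyError(f"unknown packaged design {dataset!r}")
    return io.read_design(data_path(f"{key}_design.tsv"))
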