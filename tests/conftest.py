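"""Shared fixtures: small hand-built stands and file factories."""

from __future__ import annotations

import pytest

from standspread.core_io import Stand, TreeRecord


def make_tree(tree_id, x, y, *, genus="Acer", species="rubrum", dbh=20.0, **kw):
    return TreeRecord(
        tree_id=tree_id, genus=genus, species=species, dbh_cm=dbh, x_m=x, y_m=y, **kw
    )


@pytest.fixture
def three_tree_stand() -> Stand:
    """Root candidate at the origin plus two stems on a 3-4-5 line."""
    return Stand(
        trees=[
            make_tree("R", 0.0, 0.0, pit_count=30),
            make_tree("P", 3.0, 4.0),
            make_tree("Q", 6.0, 8.0),
        ],
        area_m2=100.0,
        felling_year=2013,
    )


@pytest.fixture
def stem_csv(tmp_path):
    """Write a stem-table CSV from rows of dicts and return its path."""

    def _write(rows, name="stems.csv"):
        import pandas as pd

        path = tmp_path / name
        pd.DataFrame(rows).to_csv(path, index=False)
        return path

    return _write
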