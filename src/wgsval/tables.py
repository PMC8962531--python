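"""Published summary tables packaged as verified fixtures.

The validation study's headline tables — stratified PPA/NPA counts in
clinical samples and pharmacogenomic star-allele concordance — are shipped as
TSVs with recorded SHA-256 checksums, so that the statistics behind them can
be recomputed offline and compared against the printed values.  Each parsed
count was cross-checked before freezing: TP/FN pairs reproduce the printed
PPA at 2 decimal places (``pool_consistent`` flags the one row that prints a
per-sample average instead), and the heterozygous/homozygous rows sum to the
compiled totals.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = ["PrintedTableFixture", "load_fixture", "available_fixtures"]


@dataclass
class PrintedTableFixture:
    table_id: str
    frame: pd.DataFrame
    description: str
    sha256: str


def _data_dir():
    return resources.files("wgsval") / "data"


def available_fixtures() -> list[str]:
    meta = json.loads((_data_dir() / "fixtures.json").read_text())
    return sorted(meta)


def load_fixture(table_id: str) -> PrintedTableFixture:
    """Load a packaged table by id, verifying its checksum.

    Raises ``KeyError`` for unknown ids and ``ValueError`` on checksum
    mismatch (a corrupted installation).
    """
    meta_all = json.loads((_data_dir() / "fixtures.json").read_text())
    try:
        meta = meta_all[table_id]
    except KeyError:
        raise KeyError(
            f"unknown table id {table_id!r}; available: {sorted(meta_all)}"
        ) from None
    raw = (_data_dir() / meta["file"]).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != meta["sha256"]:
        raise ValueError(
            f"fixture {table_id} checksum mismatch: {digest} != {meta['sha256']}"
        )
    frame = pd.read_csv(_data_dir() / meta["file"], sep="\t")
    return PrintedTableFixture(
        table_id=table_id,
        frame=frame,
        description=meta["description"],
        sha256=digest,
    )
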