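"""Packaged reference tables for the Italian wolf x dog case study.

Three small CSV fixtures ship with the package:

* ``table2`` — Y-linked STR haplotype counts per sampled group (17 haplotypes).
* ``table3`` — mtDNA control-region (CR1) haplotype counts per group
  (19 haplotypes).
* ``table4`` — the 30 putative hybrids with per-method evidence columns and
  the final consensus identification of each sample.

A fourth file, ``marker_states``, maps haplotype labels to their diagnostic
interpretation (local wolf, non-local wolf, dog, dog-shared, private) and is
editable so other populations can supply their own dictionaries.

Each fixture is integrity-checked against a SHA-256 digest recorded at
packaging time.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

_FILES = {
    "table2": "table2_y_haplotypes.csv",
    "table3": "table3_mtdna_haplotypes.csv",
    "table4": "table4_putative_hybrids.csv",
    "marker_states": "marker_states.csv",
}

_SHA256 = {
    "table2": "6f557d84726bd3ea5404c43a06ef4c4faa78bf268085bddb9510edee084be460",
    "table3": "6b4c938f2a701bfbca73eab2323ee62f8a9a403267427d4617a64212e051c8e9",
    "table4": "75eb13df549beeb9a82f7659012e40804c898a0315a337b0d240ac64ac22bc5c",
    "marker_states": "54c5d66396b94386a381e27a1c598093569d57b2491a752e8c3dab75df3d6e2a",
}

GROUPS = ["DIT", "DAP", "DCZ", "WIT", "WCZ", "WHR", "WDCZ", "HYIT"]


def _read(name: str) -> tuple[bytes, str]:
    ref = resources.files("hybridkit.data").joinpath(_FILES[name])
    raw = ref.read_bytes()
    return raw, hashlib.sha256(raw).hexdigest()


def load_fixture_tables(name: str) -> pd.DataFrame:
    """Load a packaged fixture (``table2``, ``table3``, ``table4`` or
    ``marker_states``) as a typed DataFrame, verifying its checksum.

    For the haplotype tables the trailing totals row is kept (index label
    starting with ``Total``); :func:`haplotype_counts` strips it.
    """
    if name not in _FILES:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(_FILES)}")
    raw, digest = _read(name)
    if digest != _SHA256[name]:
        raise RuntimeError(
            f"fixture {name} failed its integrity check "
            f"(sha256 {digest} != {_SHA256[name]})"
        )
    import io as _io

    df = pd.read_csv(_io.BytesIO(raw))
    if name in ("table2", "table3"):
        df = df.set_index("haplotype")
        df = df.astype(int)
    elif name == "table4":
        df = df.set_index("id")
    return df


def haplotype_counts(name: str) -> pd.DataFrame:
    """Haplotype x group count matrix of ``table2`` or ``table3`` with the
    printed totals row removed."""
    df = load_fixture_tables(name)
    return df[~df.index.str.startswith("Total")]


def printed_totals(name: str) -> pd.Series:
    """The printed per-group totals row of ``table2`` or ``table3``."""
    df = load_fixture_tables(name)
    totals = df[df.index.str.startswith("Total")]
    if len(totals) != 1:
        raise RuntimeError(f"fixture {name} has no unique totals row")
    return totals.iloc[0]


def load_marker_states() -> dict[str, dict[str, str]]:
    """Haplotype-label -> diagnostic-state dictionaries for mtDNA and Y."""
    df = load_fixture_tables("marker_states")
    out: dict[str, dict[str, str]] = {"mtdna": {}, "y": {}}
    for row in df.itertuples(index=False):
        out[row.marker][row.label] = row.state
    return out
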