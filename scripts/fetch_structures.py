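#!/usr/bin/env python
"""Download the published coordinate files used by the structure-backed tests.

Requires network access. Files land in data/structures/ as uncompressed PDB
text; the tests that measure deposited structures look for them there and
fail with a pointer to this script when they are absent.

Usage: python scripts/fetch_structures.py [PDBID ...]
"""

import sys
import urllib.request
from pathlib import Path

DEFAULT_IDS = ["7SNM", "6MI0", "3N9Y", "4JWS"]
DEST = Path(__file__).resolve().parent.parent / "data" / "structures"
URL = "https://files.rcsb.org/download/{pdb_id}.pdb"


def fetch(pdb_id: str) -> Path:
    DEST.mkdir(parents=True, exist_ok=True)
    out = DEST / f"{pdb_id.upper()}.pdb"
    if out.exists():
        print(f"{out} already present")
        return out
    url = URL.format(pdb_id=pdb_id.upper())
    print(f"fetching {url} -> {out}")
    with urllib.request.urlopen(url, timeout=60) as resp:
        out.write_bytes(resp.read())
    return out


if __name__ == "__main__":
    ids = sys.argv[1:] or DEFAULT_IDS
    for pdb_id in ids:
        fetch(pdb_id)
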