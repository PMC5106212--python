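#!/usr/bin/env python
"""Populate a local structure cache with the deposited ectodomain entries.

The analysis pipeline never downloads anything itself; accession ids in a run
config are resolved against a local cache directory only.  This script fills
that cache (requires network access):

    python scripts/fetch_depositions.py --out data/pdb_cache

It fetches the eight gamma-protocadherin ectodomain fragment depositions
(5SZL 5SZM 5SZN 5SZO 5SZP 5SZQ 5SZR 5T9T) and the five published comparison
entries (5DZW 5DZV 5DZX 5DZY 5K8R) in PDB format from RCSB.
"""

import argparse
import sys
import urllib.request
from pathlib import Path

ENTRIES = [
    "5SZL", "5SZM", "5SZN", "5SZO", "5SZP", "5SZQ", "5SZR", "5T9T",
    "5DZW", "5DZV", "5DZX", "5DZY", "5K8R",
]

URL = "https://files.rcsb.org/download/{code}.pdb"


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", default="data/pdb_cache", help="cache directory")
    args = parser.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    failed = []
    for code in ENTRIES:
        dest = out / f"{code.lower()}.pdb"
        if dest.exists():
            print(f"{code}: already cached")
            continue
        try:
            urllib.request.urlretrieve(URL.format(code=code), dest)
            print(f"{code}: fetched ({dest.stat().st_size} bytes)")
        except Exception as exc:  # noqa: BLE001
            failed.append(code)
            print(f"{code}: FAILED ({exc})", file=sys.stderr)
    if failed:
        print(f"failed: {failed}", file=sys.stderr)
        return 1
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
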