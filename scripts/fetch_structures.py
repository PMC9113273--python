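#!/usr/bin/env python
"""Download the deposited structures used by the published-case tests.

Usage::

    python scripts/fetch_structures.py [--dest data/pdb]

Requires network access to files.rcsb.org.  The downloaded files enable
the deposited-structure tests in tests/test_acceptance.py (community
counts for calmodulin, hemoglobin, annexin, glycyl-tRNA synthetase, the
ER membrane protein complex and the nicotinic receptor assemblages, plus
the hemoglobin conformational RMSD).
"""

from __future__ import annotations

import argparse
import urllib.request
from pathlib import Path

PDB_IDS = ["1EXR", "1HV4", "1GZX", "1MCX", "7EIV", "6WW7", "6CNK", "6CNJ"]
URL = "https://files.rcsb.org/download/{pdb_id}.pdb"


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--dest", type=Path,
                        default=Path(__file__).resolve().parent.parent / "data" / "pdb")
    args = parser.parse_args()
    args.dest.mkdir(parents=True, exist_ok=True)
    for pdb_id in PDB_IDS:
        target = args.dest / f"{pdb_id}.pdb"
        if target.exists():
            print(f"{pdb_id}: already present")
            continue
        print(f"{pdb_id}: downloading ...")
        with urllib.request.urlopen(URL.format(pdb_id=pdb_id), timeout=60) as resp:
            target.write_bytes(resp.read())
    print(f"done; files in {args.dest}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
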