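#!/usr/bin/env python
"""Download the deposited survey structures from the PDB (network required).

Populates ``data/structures/`` with the 22 TCR/pMHC entries plus the murine
glycan reference entry. The analysis pipeline itself never touches the
network; run this once, then curate the per-chain domain manifest
(``data/survey_manifest.tsv``) from the deposited SEQRES records before
running the survey-reproduction checks.

Usage:
    python scripts/fetch_structures.py [--out data/structures]
"""

from __future__ import annotations

import argparse
import sys
import urllib.request
from importlib import resources
from pathlib import Path

import pandas as pd


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument(
        "--out", type=Path, default=Path(__file__).resolve().parents[1] / "data" / "structures"
    )
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(
        str(resources.files("tcrsurvey").joinpath("data/table1_entries.tsv")), sep="\t"
    )
    failures = 0
    for entry in table["entry_id"]:
        dest = args.out / f"{entry}.pdb"
        if dest.exists():
            print(f"{entry}: already present")
            continue
        url = f"https://files.rcsb.org/download/{entry}.pdb"
        try:
            urllib.request.urlretrieve(url, dest)
            print(f"{entry}: fetched")
        except Exception as exc:  # noqa: BLE001
            failures += 1
            print(f"{entry}: FAILED ({exc})", file=sys.stderr)
    return 1 if failures else 0


if __name__ == "__main__":
    raise SystemExit(main())
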