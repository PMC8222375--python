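#!/usr/bin/env python
"""Convert the deposited SHIVA01 per-patient supplementary tables into the
cohort TSV layout this package analyzes.

The per-patient tables of the SHIVA01 DDA analysis are deposited on figshare
(dois 10.6084/m9.figshare.14414612 and 10.6084/m9.figshare.14331323) and are
not redistributed here.  Download them, then run e.g.::

    python scripts/convert_shiva01.py supplementary_table.xlsx \
        --out data/shiva01_cohort.tsv

The converter reads the first sheet (or a CSV/TSV) with pandas and maps its
columns onto the cohort schema (patient_id, administered_mta, ael, response,
pfs_months, pfs_event, os_months, os_event, n_drivers).  Column names in the
deposit may differ between versions; use the ``--col-*`` options to remap.
If the deposit turns out to lack the outcome columns, the score–outcome
reproduction cannot be run from it, and the cohort analyses remain validated
by the synthetic pipeline only.

Responses are normalized to PR/SD/PD (complete responses, if any, count as
PR for disease-control purposes); event flags accept 1/0, true/false, or
event/censored wording.
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from dda.cohort import CohortRecord, write_cohort_tsv  # noqa: E402

RESPONSE_MAP = {
    "pr": "PR", "partial response": "PR", "cr": "PR", "complete response": "PR",
    "sd": "SD", "stable disease": "SD",
    "pd": "PD", "progressive disease": "PD", "progression": "PD",
}


def parse_event(value) -> bool:
    s = str(value).strip().lower()
    if s in {"1", "true", "yes", "event", "progression", "death"}:
        return True
    if s in {"0", "false", "no", "censored", "censor"}:
        return False
    raise SystemExit(f"cannot interpret event flag {value!r}")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("table", type=Path, help="downloaded supplementary table (.xlsx/.csv/.tsv)")
    ap.add_argument("--out", type=Path, default=Path("data/shiva01_cohort.tsv"))
    ap.add_argument("--col-patient", default="patient_id")
    ap.add_argument("--col-mta", default="mta")
    ap.add_argument("--col-ael", default="ael")
    ap.add_argument("--col-response", default="response")
    ap.add_argument("--col-pfs", default="pfs_months")
    ap.add_argument("--col-pfs-event", default="pfs_event")
    ap.add_argument("--col-os", default="os_months")
    ap.add_argument("--col-os-event", default="os_event")
    ap.add_argument("--col-n-drivers", default=None)
    args = ap.parse_args()

    if args.table.suffix.lower() in {".xlsx", ".xls"}:
        df = pd.read_excel(args.table)
    else:
        sep = "\t" if args.table.suffix.lower() == ".tsv" else ","
        df = pd.read_csv(args.table, sep=sep)
    df.columns = [str(c).strip().lower().replace(" ", "_") for c in df.columns]

    needed = [args.col_patient, args.col_mta, args.col_ael, args.col_response,
              args.col_pfs, args.col_pfs_event, args.col_os, args.col_os_event]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SystemExit(
            f"columns {missing} not found in {sorted(df.columns)}; "
            "remap with the --col-* options"
        )

    records = []
    for _, row in df.iterrows():
        resp_raw = str(row[args.col_response]).strip().lower()
        if resp_raw not in RESPONSE_MAP:
            raise SystemExit(f"unrecognized response {row[args.col_response]!r}")
        records.append(
            CohortRecord(
                patient_id=str(row[args.col_patient]),
                administered_mta=str(row[args.col_mta]),
                ael=float(row[args.col_ael]),
                response=RESPONSE_MAP[resp_raw],
                pfs_months=float(row[args.col_pfs]),
                pfs_event=parse_event(row[args.col_pfs_event]),
                os_months=float(row[args.col_os]),
                os_event=parse_event(row[args.col_os_event]),
                n_drivers=(
                    int(row[args.col_n_drivers])
                    if args.col_n_drivers and pd.notna(row[args.col_n_drivers])
                    else None
                ),
            )
        )
    args.out.parent.mkdir(parents=True, exist_ok=True)
    write_cohort_tsv(records, args.out)
    print(f"wrote {len(records)} records to {args.out}")


if __name__ == "__main__":
    main()
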