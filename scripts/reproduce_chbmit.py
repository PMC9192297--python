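#!/usr/bin/env python
"""Run the full detection workflow on locally downloaded CHB-MIT records.

This is data-dependent tooling: it requires the CHB-MIT scalp EEG corpus
(https://physionet.org/content/chbmit/), which is not distributed with
the package, and is therefore not exercised by the test suite.  It
documents how the published-scale experiment maps onto the package API.

Expected layout (one patient directory per subject):

    <data_root>/chb01/chb01_03.edf
    <data_root>/annotations.csv        # record_id,start_s,end_s per seizure

The seizure intervals can be transcribed from the corpus's
``chbXX-summary.txt`` files ("Seizure Start Time"/"Seizure End Time"
lines, seconds from record start; the record_id is the EDF stem, e.g.
``chb01_03``).

Example:
    python scripts/reproduce_chbmit.py --data-root /data/chbmit \
        --records chb01_03 chb01_04 --protocol loro --out chbmit_report.json
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

from eegpotato.channels import SELECTED_CHANNELS_10
from eegpotato.io import load_annotations, read_edf
from eegpotato.pipeline import PipelineConfig, run_pipeline


def find_edf(root: Path, record_id: str) -> Path:
    hits = sorted(root.rglob(f"{record_id}.edf"))
    if not hits:
        raise FileNotFoundError(f"{record_id}.edf not found under {root}")
    return hits[0]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-root", type=Path, required=True)
    parser.add_argument("--records", nargs="+", required=True,
                        help="record ids, e.g. chb01_03 chb01_04")
    parser.add_argument("--annotations", type=Path, default=None,
                        help="interval sidecar (default: "
                             "<data_root>/annotations.csv)")
    parser.add_argument("--protocol", choices=["cv5", "loro"], default="cv5")
    parser.add_argument("--z-threshold", type=float, default=2.5)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("chbmit_report.json"))
    args = parser.parse_args()

    ann_path = args.annotations or args.data_root / "annotations.csv"
    annotations = load_annotations(ann_path) if ann_path.exists() else {}

    recordings = []
    for rid in args.records:
        rec = read_edf(find_edf(args.data_root, rid))
        rec.annotations = list(annotations.get(rid, []))
        missing = [c for c in SELECTED_CHANNELS_10
                   if c not in rec.channel_names]
        if missing:
            print(f"warning: {rid} lacks channels {missing}; "
                  "proceeding on the intersection")
        recordings.append(rec)

    config = PipelineConfig(
        channels=SELECTED_CHANNELS_10,
        potato_z=args.z_threshold,
        protocol=args.protocol,
        seed=args.seed,
    )
    report = run_pipeline(recordings, config)
    args.out.write_text(json.dumps(report, indent=1))
    print(json.dumps({k: v for k, v in report.items()
                      if k in ("models", "fused", "n_epochs", "n_abnormal")},
                     indent=1))


if __name__ == "__main__":
    main()
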