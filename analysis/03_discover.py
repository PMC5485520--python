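"""Assign conserved miRNAs and predict novel hairpin miRNAs, then score
both against the planted truth set."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import RUN_DIR, load_config, publish

import pandas as pd

from emmir import pipeline


def main() -> None:
    cfg = load_config()
    pipeline.run_discover(cfg)

    records = pd.read_csv(RUN_DIR / "mirna_records.tsv", sep="\t")
    truth = pd.read_csv(RUN_DIR / "sim" / "truth.tsv", sep="\t")
    called = set(records["mature_seq"])
    recovered = truth["mature_seq"].isin(called)
    n_cons = (records["kind"] == "conserved").sum()
    n_novel = (records["kind"] == "novel").sum()
    print(f"called {n_cons} conserved and {n_novel} novel miRNAs")
    print(f"recovered {recovered.sum()}/{len(truth)} planted matures "
          f"({100 * recovered.mean():.1f}%)")
    extra = called - set(truth["mature_seq"])
    print(f"calls not in the truth set: {len(extra)}")
    publish("mirna_records.tsv", "mirna_counts.tsv")


if __name__ == "__main__":
    main()
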