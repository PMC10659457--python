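"""SES screen and the full mixed-model association suite.

Reads the linked exposures (03), subjects (01) and DMN metrics (04), runs
the SES-indicator correlation screen, then fits all 11 indicators x 3
outcomes x 2 model sets (with/without SES covariates) as linear mixed
models with site and family-in-site random intercepts, and writes the
report table (CSV + text panel mirroring the two model sets).
"""

from pathlib import Path

import pandas as pd

from urbansat import render_report, run_association_suite, ses_screen
from urbansat.assoc import AssocConfig, prepare_analysis_table

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    subjects = pd.read_csv(ROOT / "world" / "subjects.csv")
    linked = pd.read_csv(ROOT / "linked.csv")
    dmn = pd.read_csv(ROOT / "dmn_metrics.csv")
    cfg = AssocConfig()

    data = prepare_analysis_table(linked, subjects, dmn)
    screen = ses_screen(data)
    screen.to_csv(ROOT / "ses_screen.csv", index=False)
    strongest = screen.loc[screen["r"].abs().idxmax()]
    print("SES screen: strongest correlation "
          f"{strongest['ses_var']} x {strongest['indicator']}: r={strongest['r']:+.3f}")

    report = run_association_suite(linked, subjects, dmn, cfg)
    report.to_csv(ROOT / "associations.csv", index=False)
    text = render_report(report, cfg)
    (ROOT / "associations.txt").write_text(text + "\n")
    print()
    print(text)
    sig = report[report["label"] == "significant"]
    print(f"\n{len(sig)} significant associations at the Bonferroni "
          f"threshold {cfg.threshold:.2e} (of {len(report)} fits)")


if __name__ == "__main__":
    main()
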