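"""Regenerate the packaged validation-cohort fixture sheets.

The sheets are synthetic reconstructions: they encode the printed summary
counts (confusion-matrix cells, concordance numerators/denominators) of a
published SCM/BF screening validation cohort as row-level call/truth CSVs.
Which individual rows are discordant is arbitrary — any assignment with the
same marginals is equivalent — so rows are assigned deterministically.

Run from the repository root:  python scripts/build_fixtures.py
"""

from pathlib import Path

import pandas as pd

OUT = Path(__file__).resolve().parents[1] / "src" / "nicscreen" / "data"

POS, NEG = "aneuploid", "euploid"


def _calls(truth_labels, fn_idx, fp_idx):
    """Flip listed positive rows to FN and listed negative rows to FP."""
    pos = [i for i, t in enumerate(truth_labels) if t == POS]
    neg = [i for i, t in enumerate(truth_labels) if t == NEG]
    out = list(truth_labels)
    for k in fn_idx:
        out[pos[k]] = NEG
    for k in fp_idx:
        out[neg[k]] = POS
    return out


def build_cohort148():
    # ICM reference: 89 triads, 29 aneuploid; WB reference: 59 triads, 18 aneuploid
    ids = [f"t{i:03d}" for i in range(1, 149)]
    reference = ["ICM"] * 89 + ["WB"] * 59
    truth = ([POS] * 29 + [NEG] * 60) + ([POS] * 18 + [NEG] * 41)
    icm_t, wb_t = truth[:89], truth[89:]
    # SCM: ICM subgroup TP27 FN2 TN51 FP9; WB subgroup TP16 FN2 TN30 FP11
    scm = _calls(icm_t, fn_idx=range(2), fp_idx=range(9)) + \
        _calls(wb_t, fn_idx=range(2), fp_idx=range(11))
    # BF: ICM subgroup TP25 FN4 TN36 FP24; WB subgroup TP16 FN2 TN26 FP15
    bf = _calls(icm_t, fn_idx=range(4), fp_idx=range(24)) + \
        _calls(wb_t, fn_idx=range(2), fp_idx=range(15))
    pd.DataFrame({"sample_id": ids, "reference": reference,
                  "classification": truth}).to_csv(OUT / "cohort148_truth.csv", index=False)
    pd.DataFrame({"sample_id": ids, "classification": scm}
                 ).to_csv(OUT / "cohort148_scm_calls.csv", index=False)
    pd.DataFrame({"sample_id": ids, "classification": bf}
                 ).to_csv(OUT / "cohort148_bf_calls.csv", index=False)


def build_cohort212():
    # 96 IVF + 116 ICSI embryos with SCM data; BF data for 63 / 85 of them.
    ids = [f"e{i:03d}" for i in range(1, 213)]
    insem = ["IVF"] * 96 + ["ICSI"] * 116
    truth_ploidy = [POS if i % 3 == 0 else NEG for i in range(212)]
    truth_sex = ["XX" if i % 2 == 0 else "XY" for i in range(212)]

    def flip_p(label):
        return NEG if label == POS else POS

    def flip_s(label):
        return "XY" if label == "XX" else "XX"

    # SCM ploidy concordance: IVF 81/96 (15 off), ICSI 98/116 (18 off)
    # SCM sex concordance: IVF 95/96 (1 off), ICSI 113/116 (3 off)
    scm_p = list(truth_ploidy)
    scm_s = list(truth_sex)
    for i in list(range(15)) + list(range(96, 96 + 18)):
        scm_p[i] = flip_p(scm_p[i])
    for i in [95] + list(range(209, 212)):
        scm_s[i] = flip_s(scm_s[i])
    # BF available: first 63 IVF, first 85 ICSI.
    # ploidy: IVF 43/63 (20 off), ICSI 60/85 (25 off); sex: 53/63 (10), 78/85 (7)
    bf_rows = list(range(63)) + list(range(96, 96 + 85))
    bf_p = {i: truth_ploidy[i] for i in bf_rows}
    bf_s = {i: truth_sex[i] for i in bf_rows}
    for i in list(range(20)) + list(range(96, 96 + 25)):
        bf_p[i] = flip_p(bf_p[i])
    for i in list(range(53, 63)) + list(range(174, 181)):
        bf_s[i] = flip_s(bf_s[i])

    pd.DataFrame({"sample_id": ids, "insemination": insem,
                  "classification": truth_ploidy, "sex": truth_sex}
                 ).to_csv(OUT / "cohort212_truth.csv", index=False)
    pd.DataFrame({"sample_id": ids, "classification": scm_p, "sex": scm_s}
                 ).to_csv(OUT / "cohort212_scm_calls.csv", index=False)
    pd.DataFrame({"sample_id": [ids[i] for i in bf_rows],
                  "classification": [bf_p[i] for i in bf_rows],
                  "sex": [bf_s[i] for i in bf_rows]}
                 ).to_csv(OUT / "cohort212_bf_calls.csv", index=False)


def build_wb64():
    # 64 WB-SCM pairs: TN 34/42 (8 FP), TP 21/22 (1 FN)
    ids = [f"w{i:03d}" for i in range(1, 65)]
    truth = [POS] * 22 + [NEG] * 42
    scm = _calls(truth, fn_idx=range(1), fp_idx=range(8))
    pd.DataFrame({"sample_id": ids, "classification": truth}
                 ).to_csv(OUT / "wb64_truth.csv", index=False)
    pd.DataFrame({"sample_id": ids, "classification": scm}
                 ).to_csv(OUT / "wb64_scm_calls.csv", index=False)


if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    build_cohort148()
    build_cohort212()
    build_wb64()
    print(f"fixtures written to {OUT}")
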