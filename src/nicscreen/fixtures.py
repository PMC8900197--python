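"""Packaged validation-cohort fixture sheets.

Synthetic reconstructions of the printed summary counts of a published
SCM/BF screening validation cohort, as row-level call/truth CSVs (see
``scripts/build_fixtures.py`` in the repository for how the rows are laid
out). They let the diagnostics stage be exercised end to end without any
simulation or data download:

* ``cohort148`` — 148 embryo triads scored against an inner-cell-mass
  (n=89) or whole-blastocyst (n=59) gold standard; SCM and BF call sheets.
* ``cohort212`` — 212 embryos (96 IVF, 116 ICSI) with ploidy and sex
  calls for SCM (all) and BF (63 + 85).
* ``wb64`` — 64 whole-blastocyst/SCM pairs.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

__all__ = ["load_fixture", "FIXTURES"]

FIXTURES = {
    "cohort148_truth", "cohort148_scm_calls", "cohort148_bf_calls",
    "cohort212_truth", "cohort212_scm_calls", "cohort212_bf_calls",
    "wb64_truth", "wb64_scm_calls",
}


def load_fixture(name: str) -> pd.DataFrame:
    """Load one packaged fixture sheet by name (see FIXTURES)."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}")
    resource = files("nicscreen.data").joinpath(f"{name}.csv")
    with resource.open("r") as fh:
        return pd.read_csv(fh, dtype=str, keep_default_na=False)
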