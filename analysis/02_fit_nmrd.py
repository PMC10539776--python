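#!/usr/bin/env python
"""Stage 2: extract site-specific T1 and correlation times.

Fits every synthetic inversion-recovery series with a three-parameter
exponential, assembles per-proton relaxation dispersion curves, and fits the
two-contribution dispersion model in the high-field window to obtain the
site-specific correlation times.  The headline finding this emulates: the
correlation times of adenine, flavin and linker protons coincide at about a
nanosecond, i.e. the FAD structure tumbles as one rigid, compact unit.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from fadcidnp import io_tables
from fadcidnp.nmrd_fit import NMRDCurve, RelaxationDecaySeries, fit_decay, fit_dispersion

ROOT = Path(__file__).resolve().parent.parent / "results"
WINDOW = (0.56, 16.44)


def main() -> None:
    df, meta = io_tables.read_table(ROOT / "synthetic" / "decays.tsv",
                                    required=["proton", "B_T", "tau_vd_s", "intensity"])
    truth, _ = io_tables.read_table(ROOT / "synthetic" / "nmrd_truth.tsv")
    truth = truth.set_index("proton")["tau_c_s"]
    curves, fit_rows = [], []
    for proton, sub in df.groupby("proton", sort=False):
        Bs, T1s, errs = [], [], []
        for B, ss in sub.groupby("B_T"):
            ss = ss.sort_values("tau_vd_s")
            fit = fit_decay(RelaxationDecaySeries(str(proton), float(B),
                                                  ss["tau_vd_s"].to_numpy(),
                                                  ss["intensity"].to_numpy()))
            if not fit.flagged:
                Bs.append(float(B)); T1s.append(fit.T1); errs.append(fit.T1_err)
        curve = NMRDCurve(str(proton), np.array(Bs), np.array(T1s), np.array(errs))
        curves.append(curve)
        p = fit_dispersion(curve, *WINDOW)
        fit_rows.append(
            {"proton": proton, "R1_s": p.R1, "R1_inf_s": p.R1_inf,
             "tau_c_ns": p.tau_c * 1e9, "tau_c_err_ns": (p.tau_c_err or np.nan) * 1e9,
             "tau_c_truth_ns": truth[proton] * 1e9}
        )
        print(f"{proton:4s}  tau_c = {p.tau_c * 1e9:5.3f} ns "
              f"(truth {truth[proton] * 1e9:5.3f})  R1 = {p.R1:5.2f} /s")
    io_tables.write_nmrd_curves(ROOT / "nmrd_curves.tsv", curves, meta=meta)
    io_tables.write_table(ROOT / "nmrd_fits.tsv", pd.DataFrame(fit_rows),
                          meta={"window_T": f"{WINDOW[0]}:{WINDOW[1]}", **meta})
    taus = [r["tau_c_ns"] for r in fit_rows]
    print(f"correlation times span {min(taus):.2f}-{max(taus):.2f} ns: "
          "all sites tumble together (rigid, compact structure)")


if __name__ == "__main__":
    main()
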