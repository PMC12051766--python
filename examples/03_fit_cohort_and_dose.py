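"""Generate a synthetic cohort, fit the MTP reference, compute doses.

The cohort generator draws per-organ effective half-lives from the
published cohort distributions, observes sparse noisy activity curves on
clinical schedules, and keeps the generating truth.  Fitting the
biexponential model (uptake term fixed to the population prior) recovers
T_eff and TIA; the S-value fixture then converts TIA to absorbed dose.
"""

import numpy as np

from istpdose import (
    CohortConfig,
    PhysicalDecay,
    PopulationPrior,
    batch_fit,
    default_svalue_fixture,
    dose_table,
    generate_cohort,
)

cfg = CohortConfig(n_patients=22, seed=7, noise_cv=0.05)
cohort = generate_cohort(cfg)
print(f"cohort: {cfg.n_patients} patients, {len(cohort.features)} cycles, "
      f"{len(cohort.curves)} organ curves")

prior = PopulationPrior.default_fixture()
fits = batch_fit(cohort.curves, prior, PhysicalDecay.lu177())
print(f"fits: {len(fits.estimates)} ({fits.convergence_rate:.0%} converged), "
      f"{len(fits.skipped)} skipped")

merged = fits.estimates.merge(
    cohort.truth, on=["patient_id", "cycle", "organ"], suffixes=("", "_true")
)
err = np.abs(merged["teff_hours"] / merged["teff_hours_true"] - 1.0) * 100.0
print(f"T_eff recovery at 5% measurement noise: median |error| {err.median():.2f}%")

doses = dose_table(fits.estimates, default_svalue_fixture())
print("mean absorbed dose per organ (synthetic S-values):")
for organ, grp in doses.groupby("organ"):
    print(f"  {organ:13s} {grp['dose_Gy'].mean():7.3f} Gy "
          f"(range {grp['dose_Gy'].min():.3f}-{grp['dose_Gy'].max():.3f})")
# Kidneys receive a few Gy per cycle, spleen sub-Gy, liver centi-Gy —
# the magnitude ordering expected for Lu-177 PSMA therapy.
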