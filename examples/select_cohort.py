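"""Apply the phenotype and quality-control subject selections.

The fQC variant keeps eyes-open males with a recorded FIQ whose head motion
(mean framewise displacement) is not a median+3*MAD outlier; the later
age-window/site-size selection is meant to run after harmonization.
"""

from combatcv import (
    SyntheticConfig,
    apply_age_and_site_selection,
    generate_cohort,
    select_fqc,
    select_minsc,
    selection_report,
)

config = SyntheticConfig(n_sites=3, subjects_per_site=120, fd_outlier_rate=0.08)
phenotypes = generate_cohort(config, seed=5)

minsc = select_minsc(phenotypes)
fqc = select_fqc(phenotypes)
fqc_as = apply_age_and_site_selection(fqc, phenotypes, age_window=(9, 20),
                                      min_site_n=30)

report = selection_report(
    phenotypes, {"all": phenotypes["subject_id"].tolist(),
                 "minSC": minsc, "fQC": fqc, "fQCas": fqc_as},
)
print(report[report["site"] == "TOTAL"].to_string(index=False))
# Each row is one selection stage; fQC < minSC because of the eyes-open,
# FIQ and motion filters, and fQCas further narrows age and drops sites
# left with fewer than 30 subjects.
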