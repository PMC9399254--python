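"""Published aggregate margins from a national OAT overdose cohort.

A large English primary-care cohort of opioid-agonist-treatment
recipients (20,898 adults, 1998-2017, linked hospital and mortality
records) published stratum-level person-years and non-fatal overdose
counts by risk window and modality.  Those printed margins are inputs
here: crude rate ratios and rates recomputed from them validate this
package's rate arithmetic, and the published weighted modality estimate
feeds the E-value bias analysis.  Patient-level data are not public and
are not reproduced.
"""

# person-years and non-fatal overdose events (all events per patient)
EVENT_STRATA = {
    "in": {"person_years": 25206, "events": 3930},
    "out": {"person_years": 33170, "events": 7478},
    "in_1_4": {"person_years": 3598, "events": 1861},
    "in_gt4": {"person_years": 21608, "events": 2069},
    "out_1_4": {"person_years": 3492, "events": 3639},
    "out_gt4": {"person_years": 29677, "events": 3839},
}

# by modality, all events
MODALITY_STRATA = {
    ("all", "methadone"): {"person_years": 64232, "events": 11360},
    ("all", "buprenorphine"): {"person_years": 19623, "events": 1613},
    ("in", "methadone"): {"person_years": 25760, "events": 4158},
    ("in", "buprenorphine"): {"person_years": 5560, "events": 385},
    ("out", "methadone"): {"person_years": 38472, "events": 7202},
    ("out", "buprenorphine"): {"person_years": 14063, "events": 1228},
}

# first events only (incidence), censored at the event
INCIDENCE_STRATA = {
    "in": {"person_years": 21798, "events": 1602},
    "out": {"person_years": 27219, "events": 2665},
}

COHORT_TOTALS = {
    "n_patients": 20898,
    "person_years": 83856,
    "admissions": 12973,
    "patients_with_overdose": 4512,
}

# published weighted (IPW) buprenorphine-vs-methadone rate ratio, all periods
WEIGHTED_MODALITY_RR = {"rr": 0.39, "ci_low": 0.38, "ci_high": 0.41}
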