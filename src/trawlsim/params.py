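"""Default biological, fishery and economic parameters.

Literature-derived constants for the three demersal target species of the
Strait of Sicily trawl fishery: deep-water rose shrimp (DPS,
*Parapenaeus longirostris*), European hake (HKE, *Merluccius merluccius*)
and red mullet (MUT, *Mullus barbatus*).  Lengths are handled in mm
throughout the package; the length-weight power law returns grams.
"""

from __future__ import annotations

from trawlsim.economics import CostModel, PriceSchedule, SexParams, SpeciesParams

SPECIES = ("DPS", "HKE", "MUT")

#: cohort components fitted per sex: 3 for DPS and HKE, 2 for MUT
N_COHORTS = {"DPS": 3, "HKE": 3, "MUT": 2}

#: default length-class bin width (mm) used when building LFDs
CLASS_WIDTH = {"DPS": 1.0, "HKE": 5.0, "MUT": 2.0}

DEFAULT_SPECIES_PARAMS = {
    "DPS": SpeciesParams(
        code="DPS",
        male=SexParams(linf=33.56, k=0.73, t0=-0.13, M=1.2, a=0.0034, b=2.4096),
        female=SexParams(linf=42.71, k=0.67, t0=-0.208, M=1.05, a=0.0029, b=2.4818),
        L50=15.0, L75=18.0, q=0.0022, qM=0.85,
        F_lca_mean=1.33, F_lca_sd=0.16,
    ),
    "HKE": SpeciesParams(
        code="HKE",
        male=SexParams(linf=1000.0, k=0.116, t0=-0.5, M=0.43, a=0.000003598, b=3.125),
        female=SexParams(linf=201.6, k=0.57, t0=-0.8, M=0.34, a=0.000003598, b=3.125),
        L50=120.0, L75=140.0, q=0.0018, qM=0.15,
        F_lca_mean=1.15, F_lca_sd=0.12,
    ),
    "MUT": SpeciesParams(
        code="MUT",
        male=SexParams(linf=236.1, k=0.45, t0=-0.8, M=1.0, a=0.00002648, b=2.823),
        female=SexParams(linf=33.56, k=0.73, t0=-0.13, M=1.0, a=0.00001532, b=2.942),
        L50=90.0, L75=110.0, q=0.0021, qM=0.85,
        F_lca_mean=1.47, F_lca_sd=0.17,
    ),
}

# Market prices by commercial size band (mm -> euros/kg).  The DPS schedule
# is the recorded one for the main Sicilian landing ports; HKE and MUT
# schedules are plausible defaults used by the synthetic generator.
DEFAULT_PRICES = {
    "DPS": PriceSchedule("DPS", [(0.0, 21.0, 2.5), (21.0, 25.0, 5.0),
                                 (25.0, 30.0, 8.0), (30.0, None, 16.0)]),
    "HKE": PriceSchedule("HKE", [(0.0, 150.0, 3.0), (150.0, 250.0, 6.5),
                                 (250.0, 350.0, 9.0), (350.0, None, 12.0)]),
    "MUT": PriceSchedule("MUT", [(0.0, 130.0, 3.5), (130.0, 170.0, 7.0),
                                 (170.0, None, 11.0)]),
}

#: fitted fleet fuel-cost plane TC = b0 + b_ps*PS + b_e*E used as the
#: generative truth of the synthetic fuel records
DEFAULT_COST_MODEL = CostModel(beta0=-1.607e7, beta_ps=2.200e2, beta_e=1.321e7)

# Cohort mean length (mm) and sd by species/sex/year used as generative
# defaults for synthetic length samples (survey years 2006-2010).
COHORT_MIXTURES = {
    ("DPS", "F"): {
        2006: [(14.1, 2.1), (23.4, 1.8), (26.7, 3.5)],
        2007: [(15.6, 2.4), (25.0, 2.2), (31.5, 1.9)],
        2008: [(19.9, 2.1), (24.4, 1.6), (28.8, 2.5)],
        2009: [(19.3, 3.0), (23.6, 1.6), (27.9, 2.5)],
        2010: [(15.5, 3.3), (22.8, 2.0), (30.9, 2.1)],
    },
    ("DPS", "M"): {
        2006: [(15.7, 1.8), (21.0, 1.4), (25.5, 1.6)],
        2007: [(15.7, 1.8), (21.0, 1.4), (25.5, 1.6)],
        2008: [(16.7, 1.8), (20.5, 1.4), (25.0, 1.6)],
        2009: [(15.7, 1.8), (21.0, 1.4), (25.5, 1.6)],
        2010: [(15.7, 1.8), (21.0, 1.4), (25.5, 1.6)],
    },
    ("HKE", "F"): {
        2006: [(100.0, 16.0), (200.0, 44.8), (320.0, 110.5)],
        2007: [(105.0, 16.0), (200.0, 44.8), (320.0, 110.5)],
        2008: [(100.0, 16.0), (200.0, 31.3), (320.0, 110.5)],
        2009: [(100.0, 16.0), (200.0, 31.3), (320.0, 110.5)],
        2010: [(120.0, 16.0), (220.0, 31.3), (340.0, 110.5)],
    },
    ("HKE", "M"): {
        2006: [(100.0, 19.0), (190.0, 44.2), (280.0, 59.3)],
        2007: [(105.0, 19.0), (190.0, 44.2), (280.0, 59.3)],
        2008: [(100.0, 19.0), (190.0, 30.9), (280.0, 59.3)],
        2009: [(100.0, 19.0), (190.0, 30.9), (280.0, 59.3)],
        2010: [(120.0, 19.0), (210.0, 30.9), (300.0, 59.3)],
    },
    ("MUT", "F"): {
        2006: [(144.0, 10.0), (169.0, 21.0)],
        2007: [(165.0, 15.0), (176.0, 20.0)],
        2008: [(149.0, 12.0), (175.0, 20.0)],
        2009: [(159.6, 17.0), (187.0, 19.0)],
        2010: [(144.0, 10.0), (169.0, 21.0)],
    },
    ("MUT", "M"): {
        2006: [(130.9, 7.0), (151.0, 14.0)],
        2007: [(123.0, 7.0), (150.0, 14.0)],
        2008: [(134.0, 9.0), (154.0, 14.0)],
        2009: [(122.0, 8.0), (155.0, 13.0)],
        2010: [(134.2, 8.0), (155.0, 13.0)],
    },
}

#: depth strata (m) of the stratified random survey design
SURVEY_STRATA_BOUNDS = [(10.0, 50.0), (51.0, 100.0), (101.0, 200.0),
                        (200.0, 500.0), (500.0, 800.0)]
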