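# Default configuration: Beijing 2006 population and household parameters.
#
# Distribution families: truncnorm = normal truncated at [low, high];
# lognormal = lognormal matched to the given (mean, sd) moments.
# Units are annotated per key.  Every value here is editable; the packaged
# defaults reproduce the published demographic constants and parameter
# table for this application.

population:
  urban_fraction: 0.84
  male_fraction: 0.511
  smoker_fraction: 0.311
  employed_fraction: 0.72
  school_age_fraction: 0.09
  ceiling_height_m: 2.7
  deposition_rate_particle: 0.2     # 1/h, particle phase
  erf_chimney: 0.10                 # coal users with chimneys
  erf_hood: 0.50                    # regular exhaust-hood users
  workplace:
    ach: 1.0                        # 1/h
    volume_m3: 30.0                 # per occupant
    penetration: 0.9
  breathing:
    daily_volume_m3: 16.0
    multipliers: {home: 0.8, work: 1.0, outdoor: 1.5}
  regions:
    urban:
      ach:                {mean: 0.31, sd: 0.23, family: truncnorm, low: 0.01}   # 1/h
      floor_area_m2:      {mean: 53.4, sd: 24.6, family: truncnorm, low: 5.0}
      penetration:        {mean: 0.90, sd: 0.06, family: truncnorm, low: 0.0, high: 1.0}
      time_home_h:        {mean: 16.0, sd: 2.0,  family: truncnorm, low: 0.0, high: 24.0}
      time_work_school_h: {mean: 5.45, sd: 3.01, family: truncnorm, low: 0.0, high: 24.0}
      smoking_cigs_per_day: {mean: 9.0, sd: 19.0, family: lognormal}             # household total
      wood_crop_kg_day:   {mean: 0.0,  sd: 0.0}
      coal_kg_day:        {mean: 0.0,  sd: 0.0}
      lpg_kg_day:         {mean: 0.4,  sd: 0.2,  family: lognormal}
      coal_user_fraction: 0.0
      hood_user_fraction: 0.30          # 70% use hoods only sometimes or never
      home_smoking_ban_fraction: 0.20
      workplace_smoking_ban_fraction: 0.30
    rural:
      ach:                {mean: 0.59, sd: 0.47, family: truncnorm, low: 0.01}
      floor_area_m2:      {mean: 128.9, sd: 59.3, family: truncnorm, low: 5.0}
      penetration:        {mean: 0.90, sd: 0.06, family: truncnorm, low: 0.0, high: 1.0}
      time_home_h:        {mean: 16.0, sd: 2.0,  family: truncnorm, low: 0.0, high: 24.0}
      time_work_school_h: {mean: 5.45, sd: 3.01, family: truncnorm, low: 0.0, high: 24.0}
      smoking_cigs_per_day: {mean: 9.0, sd: 19.0, family: lognormal}
      wood_crop_kg_day:   {mean: 4.00, sd: 2.61, family: lognormal}
      coal_kg_day:        {mean: 2.0,  sd: 1.5,  family: lognormal}
      lpg_kg_day:         {mean: 0.0,  sd: 0.0}
      # coal users: 11% of the total population, all rural -> 0.11 / 0.16
      coal_user_fraction: 0.6875
      hood_user_fraction: 0.0
      home_smoking_ban_fraction: 0.10
      workplace_smoking_ban_fraction: 0.30

risk:
  urr: 4.49                 # unit relative risk at 100 ug/m3-year lifetime BaP
  urr_alternative: 1.30     # Asian-population alternative
  reference_exposure: 100.0 # ug/m3-year

cleaner:
  cadr_m3_h: 134.0          # market-average clean-air delivery rate
  hours_per_day: 16.0       # typical daily operation (time spent at home)

who:
  bap_guideline_ng_m3: 1.2        # least strict BaP guideline value
  bap_fraction_of_baepeq: 0.381   # average BaP share of total B[a]Peq

fuel_energy_mj_per_kg: {wood_crop: 16.0, coal: 23.0, lpg: 46.0}

correlated_outdoor: true    # one shared quantile per season across congeners
lifetime_years: 70.0
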