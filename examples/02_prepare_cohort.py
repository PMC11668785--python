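"""Prepare an analysis cohort from raw measurements.

Runs the preparation pipeline — monthly resampling, time-zero at the first
eGFR, exclusions, ESKD/death adjudication (sustained eGFR <= 15 without
recovery > 17, or dialysis/transplant), and the >=3-entries-per-analyte
density filter — and prints the exclusion tally and the adjudicated event mix.
"""

from collections import Counter

from crlandmark import (SimulationConfig, simulate_cohort, prepare_cohort,
                        CohortConfig)

cfg = SimulationConfig(n_patients=400, seed=7)
measurements, demographics, outcomes, _ = simulate_cohort(cfg)

timelines, tally = prepare_cohort(measurements, demographics, outcomes,
                                  CohortConfig(variant="dense3"))

print(f"patients retained   : {len(timelines)}")
print(f"exclusion tally     : {tally}")
causes = Counter(tl.cause for tl in timelines)
print(f"adjudicated outcomes: censored={causes[0]}, ESKD={causes[1]}, "
      f"death={causes[2]}")
tl = timelines[0]
print(f"\nexample patient {tl.patient_id}: age {tl.age_at_time0:.0f}, "
      f"cause {tl.cause}, event/censor time {tl.event_time:.2f}y, "
      f"eGFR months observed: {len(tl.series['egfr'])}")
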