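"""The non-mechanistic baseline: Gaussian-process regression on meal pairs.

Maps (pre-meal glucose, carbohydrate grams) to the first post-meal reading,
warm-starting on 50 meals and then forecasting each new meal before
absorbing it.  Printed: how many meals qualify under the strict pairing
rules and the sequential forecast error.
"""

import numpy as np

from glucoda.gpmr import InsufficientDataError, extract_meal_pairs, sequential_evaluate
from glucoda.synth import CohortConfig, simulate_patient

patient = simulate_patient(CohortConfig(model_id="ultradian", regime="typical",
                                        n_days=28, seed=5))
pairs = extract_meal_pairs(patient.timeline)
print(f"meals recorded: {len(patient.timeline.meals)}; "
      f"qualifying (pre within 15 min, post 45-180 min): {len(pairs)}")

try:
    result = sequential_evaluate(pairs, initial_train_n=50)
except InsufficientDataError as e:
    print(f"insufficient data for the GP baseline: {e}")
else:
    print(f"sequential forecasts made: {len(result.forecasts)}")
    print(f"GPMR MSE: {result.mse:.1f} (mg/dl)^2 "
          f"(rmse {np.sqrt(result.mse):.1f} mg/dl)")
# Unlike the filter, this baseline can only forecast meals that carry both a
# qualifying pre- and post-measurement -- sparse regimes starve it of data.
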