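#!/usr/bin/env python
"""Replicated validation studies (reduced replicate counts for a quick look).

Runs the SPDE oracle comparison and 25-replicate versions of the recovery,
selection, lag-recovery and mitigation-ordering studies; the full
100-replicate versions back the acceptance checks
(`python scripts/acceptance.py`).
"""

import json
import warnings

warnings.filterwarnings("ignore")

from bycatch import evaluation as ev

print("SPDE oracle:", json.dumps(ev.spde_oracle_metrics(seed=0), indent=1))
print("\nfixed-effect recovery (25 reps):",
      json.dumps(ev.recovery_study(n_reps=25, seed=1), indent=1))
print("\nstepwise selection (25 reps):",
      json.dumps(ev.selection_study(n_reps=25, seed=1), indent=1))
print("\nlag-2 recovery (25 reps):",
      json.dumps(ev.lag_study(n_reps=25, seed=1), indent=1))
print("\nmitigation ordering (25 reps):",
      json.dumps(ev.mitigation_ordering_study(n_reps=25, seed=1), indent=1))
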