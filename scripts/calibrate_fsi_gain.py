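"""One-time calibration of the default FSI drive.

The circuit data fix the FSI -> MSN weights but not how the FSI rate
follows the cortical rate.  The package's default is a threshold-linear
model lam_FSI = gain * max(0, lam_CTX - threshold): FSIs have a much higher
rheobase than MSNs and are nearly silent at low cortical drive, then follow
cortex steeply.  The gain is fixed at 3.0 (FSI rates reach ~30 Hz at the
top of the standard sweep); this script calibrates the activation threshold
so that the multiplicative-scenario reference sweep (default weights,
lam_CTX 0-20 Hz) crosses from a D1 to a D2 bias at 13 Hz.

Run:  python scripts/calibrate_fsi_gain.py
The resulting threshold is recorded as DEFAULT_FSI_THRESHOLD in
striatal_dtt.meanfield (currently 9.4, i.e. the bisection result rounded to
the sweep resolution of 0.1 Hz).
"""

import numpy as np

from striatal_dtt.meanfield import EffectiveWeights, FsiDriveModel, ScenarioInput
from striatal_dtt.dtt import sweep_delta_msn

TARGET_DTT = 13.0
GAIN = 3.0
GRID = np.arange(0.0, 20.0 + 1e-9, 0.1)


def mult_dtt(threshold: float) -> float | None:
    drv = FsiDriveModel(mode="proportional", gain=GAIN, threshold=threshold)
    res = sweep_delta_msn(
        EffectiveWeights(), ScenarioInput("multiplicative", fsi_drive=drv), grid=GRID
    )
    return res.dtt


def main() -> None:
    lo, hi = 5.0, 12.0  # DTT increases monotonically with the threshold
    for _ in range(20):
        mid = 0.5 * (lo + hi)
        d = mult_dtt(mid)
        if d is None or d < TARGET_DTT:
            lo = mid
        else:
            hi = mid
    threshold = 0.5 * (lo + hi)
    rounded = round(threshold, 1)
    print(f"gain            = {GAIN}")
    print(f"threshold       = {threshold:.4f} Hz  (recorded as {rounded})")
    print(f"resulting DTT   = {mult_dtt(rounded):.3f} Hz (target {TARGET_DTT})")


if __name__ == "__main__":
    main()
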