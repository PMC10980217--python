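#!/usr/bin/env python
"""Shaker reference levels and trial timelines.

Converts the seven protocol frequencies to reference accelerations under
both conversion variants, builds the validity and reliability timelines,
and exports the reference levels and the per-second validity reference
trace.  The as-used conversion spans 4.4 mg at 0.6 Hz to 124.7 mg at
3.2 Hz; the printed-formula variant is exactly pi times larger.
"""

from pathlib import Path

import pandas as pd

from shakerval import (
    ShakerConfig,
    build_reliability_sequence,
    build_validity_protocol,
    reference_acceleration_mg,
)
from shakerval.shaker import VALIDITY_FREQUENCIES_HZ, reference_trace_frame

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    used = ShakerConfig(conversion_variant="as_used")
    printed = ShakerConfig(conversion_variant="as_printed")

    levels = pd.DataFrame(
        {
            "frequency_hz": VALIDITY_FREQUENCIES_HZ,
            "reference_mg_as_used": [
                round(reference_acceleration_mg(f, used), 1)
                for f in VALIDITY_FREQUENCIES_HZ
            ],
            "reference_mg_as_printed": [
                round(reference_acceleration_mg(f, printed), 1)
                for f in VALIDITY_FREQUENCIES_HZ
            ],
        }
    )
    levels.to_csv(RESULTS / "reference_levels.csv", index=False)
    print("reference accelerations by shaker speed (mg):")
    print(levels.to_string(index=False))

    validity = build_validity_protocol(used)
    batch = build_reliability_sequence(0.6, 5)
    print(
        f"\nvalidity trial: {len(validity.segments)} segments, "
        f"{validity.duration_s:.0f} s total "
        f"({len(validity.oscillation_segments)} oscillation blocks)"
    )
    print(f"reliability batch (5 trials at one speed): {batch.duration_s:.0f} s")

    validity.save(RESULTS / "protocol_validity.yaml")
    reference_trace_frame(validity, used).to_csv(
        RESULTS / "reference_trace_validity.csv", index=False
    )
    print(f"\nwrote reference levels, protocol and trace to {RESULTS}")


if __name__ == "__main__":
    main()
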