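"""Quantify the demo subject: destripe, segment, measure, compute RCC.

Reads results/01_demo_subject/ (run 01 first) and writes the measured
metric quadruples plus the reactive capillary coefficient to
results/02_subject_metrics/metrics.json, alongside the segmentation
mask and skeleton for the baseline state.
"""

import json
from pathlib import Path

import numpy as np
import tifffile

from rhocta import (
    RunConfig,
    analyze_image,
    compute_rcc,
    read_enface_tiff,
    remove_stripes,
    segment_vessels,
    skeletonize,
)

IN = Path(__file__).resolve().parents[1] / "results" / "01_demo_subject"
OUT = Path(__file__).resolve().parents[1] / "results" / "02_subject_metrics"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = RunConfig()
    measured = {}
    for state in ("baseline", "compressed", "hyperemia"):
        image = read_enface_tiff(IN / f"{state}.tif", state=state)
        measured[state] = analyze_image(image, config)

    rcc = compute_rcc(measured["baseline"], measured["hyperemia"])
    payload = {
        state: {
            "vd": m.vd,
            "lvn": m.lvn,
            "nbp": m.nbp,
            "diameter_um": m.diameter_um if m.lvn > 0 else None,
        }
        for state, m in measured.items()
    }
    payload["rcc"] = rcc.rcc
    (OUT / "metrics.json").write_text(json.dumps(payload, indent=2) + "\n")

    # save the baseline mask and skeleton for visual inspection
    baseline = remove_stripes(read_enface_tiff(IN / "baseline.tif", state="baseline"))
    mask = segment_vessels(baseline)
    skel = skeletonize(mask)
    tifffile.imwrite(OUT / "baseline_mask.tif", (mask.mask * 255).astype(np.uint8))
    tifffile.imwrite(OUT / "baseline_skeleton.tif", (skel.skeleton * 255).astype(np.uint8))
    print(json.dumps(payload, indent=2))


if __name__ == "__main__":
    main()
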