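"""Synthesize a demo subject: baseline / compressed / hyperemia fields.

Writes 1.5015 mm (231 px) en-face images with default speckle and
stripe artifacts plus the noise-free ground truth, under
results/01_demo_subject/.
"""

import json
from pathlib import Path

from rhocta import (
    ArtifactParams,
    add_artifacts,
    generate_network,
    render_enface,
    write_enface_tiff,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "01_demo_subject"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    network = generate_network(field_size_mm=1.5015, target_density=0.25, seed=SEED)
    truth = {}
    for state in ("baseline", "compressed", "hyperemia"):
        image, tm = render_enface(network, state)
        noisy = add_artifacts(image, ArtifactParams(seed=SEED + 100))
        write_enface_tiff(noisy, OUT / f"{state}.tif")
        truth[state] = {
            "vd": 100.0 * tm.area_fraction,
            "lvn": tm.centerline_length_per_area,
            "nbp": tm.branch_count,
        }
    (OUT / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
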