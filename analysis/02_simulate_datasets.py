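"""Generate the seeded easy- and hard-preset spot datasets.

Each dataset is 384 spot peak lists (intact + digested x train + score x
48 positive + 48 negative) plus a manifest, written under
scratch/datasets/<preset>.  Reruns are byte-identical.
"""

from pathlib import Path

import numpy as np

from maldisort.peaklist_io import read_peaklist
from maldisort.simulate import SimConfig, generate_dataset

SEED = 42
OUT = Path(__file__).resolve().parents[1] / "scratch" / "datasets"


def main() -> None:
    for preset in ("easy", "hard"):
        cfg = SimConfig(seed=SEED, preset=preset)
        manifest, manifest_path = generate_dataset(cfg, OUT / preset)
        for mode in ("intact", "digested"):
            entries = manifest.select(mode=mode)
            counts = [len(read_peaklist(e.file, mode=mode)) for e in entries[:16]]
            print(f"{preset}/{mode}: {len(entries)} spots, "
                  f"~{int(np.mean(counts))} peaks per spot")
        print(f"  manifest: {manifest_path}")


if __name__ == "__main__":
    main()
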