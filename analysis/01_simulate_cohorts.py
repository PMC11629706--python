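#!/usr/bin/env python
"""Generate the synthetic study cohorts.

Writes the five named scenarios (null, harmful signal with true OR 1.63,
protective signal with true OR 0.70, directional-pleiotropy trap,
high-heterogeneity trap) as exposure/outcome summary-statistics TSVs with
block-structured LD matrices under results/fixtures/, and prints what each
scenario encodes.  Sample sizes emulate a microbiome-exposure MR design:
exposure GWAS n = 18,340; outcome GWAS 1,086 cases / 147,221 controls.
"""

import json
from pathlib import Path

from mrgj.simulate import make_fixture_suite

OUT = Path(__file__).resolve().parents[1] / "results" / "fixtures"
SEED = 20241126


def main() -> None:
    manifest = make_fixture_suite(OUT, seed=SEED)
    print(f"wrote {len(manifest['scenarios'])} scenarios under {OUT}")
    print(f"{'scenario':<24}{'j_snps':>7}{'true OR':>9}  pleiotropy")
    for name, meta in manifest["scenarios"].items():
        print(f"{name:<24}{meta['j_snps']:>7}{meta['true_or']:>9.2f}  {meta['pleiotropy']}")
    print(f"\nmanifest: {OUT / 'manifest.json'}")


if __name__ == "__main__":
    main()
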