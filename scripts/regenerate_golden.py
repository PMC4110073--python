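#!/usr/bin/env python
"""Regenerate the checked-in golden fixture bundle under tests/data/golden.

With --check, regenerates into a temporary directory and asserts byte
identity with the checked-in files instead of overwriting them.
"""
import argparse
import filecmp
import os
import sys
import tempfile

from truncscore import FixtureConfig, generate_bundle

GOLDEN_SEED = 20140724
GOLDEN_DIR = os.path.join(os.path.dirname(__file__), "..", "tests", "data", "golden")


def main() -> int:
    ap = argparse.ArgumentParser()
    ap.add_argument("--check", action="store_true")
    args = ap.parse_args()
    cfg = FixtureConfig(seed=GOLDEN_SEED)
    golden = os.path.abspath(GOLDEN_DIR)
    if not args.check:
        paths = generate_bundle(cfg, golden)
        for p in paths.values():
            print(f"wrote {p} ({os.path.getsize(p)} bytes)")
        return 0
    with tempfile.TemporaryDirectory() as tmp:
        paths = generate_bundle(cfg, tmp)
        bad = [
            os.path.basename(p)
            for p in paths.values()
            if not filecmp.cmp(p, os.path.join(golden, os.path.basename(p)), shallow=False)
        ]
    if bad:
        print(f"golden files out of date: {bad}", file=sys.stderr)
        return 1
    print("golden bundle is byte-identical to a fresh regeneration")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
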