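#!/usr/bin/env python
"""Wrapper module for bismark (methylation)."""
import pathlib
import sys

if __name__ == "__main__":
    try:
        from flowlite.wrappers.runner import main
    except ImportError:
        sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[2]))
        from flowlite.wrappers.runner import main
    raise SystemExit(main(pathlib.Path(__file__).stem))
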