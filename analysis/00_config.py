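"""Shared settings for the analysis drivers.

One synthetic study is threaded through all stages: a 2 × 1 Mb genome, six
leaf cell types × 400 nuclei, signal-to-noise 5, 60 planted peaks (40%
broad) plus 10 nucleosomal decoys.  Stages write their tables under
``results/`` and later stages read them back, so run the scripts in order.
"""

from pathlib import Path

SEED = 7
CELLS_PER_TYPE = 400
SNR = 5.0
RESULTS = Path(__file__).resolve().parent.parent / "results"
DATA = RESULTS / "data"
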