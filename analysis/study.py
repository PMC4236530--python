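"""Shared configuration for the analysis scripts.

One desk-scale study: 6 000 persons (60% decedents with a death in
2008-09, the rest background population), nine financial years of
admissions at the default calibration, and the error-injected master
linkage key.  Bulk datasets go under ``scratch/`` (regenerable at any
time from the seed); the report tables land under ``results/tables``.
"""

from pathlib import Path

from slklink.synth import SynthConfig

ROOT = Path(__file__).resolve().parent.parent
DATA_DIR = ROOT / "scratch" / "study" / "data"
LINKS_DIR = ROOT / "scratch" / "study" / "links"
TABLES_DIR = ROOT / "results" / "tables"

SEED = 581

CONFIG = SynthConfig(n_persons=6000, p_decedent=0.6, seed=SEED)
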