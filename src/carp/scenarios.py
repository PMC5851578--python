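"""Reference synthetic-benchmark scenarios.

Two planted-genome study conditions exercise the whole pipeline at desk
scale and are shared by the test suite and the acceptance script:

* ``family_discovery_spec`` — a ~1 Mb assembly with five dispersed TE
  families spanning the 20-200 copy and ~95-99 % pairwise identity range
  (one 5'-truncated, as LINE insertions typically are), three long
  low-copy segmental duplications, a host gene family with four paralogs,
  and a low-copy autonomous LINE-like family whose ancestor carries an
  intact ORF2 embedding a reverse-transcriptase protein.

* ``high_copy_spec`` — a ~1 Mb assembly dominated by a single 2,500-copy
  novel element family (absent from any reference library) plus three
  segmental duplications, exercising the copy-number triage that separates
  SDs from high-copy novel TEs.
"""

from __future__ import annotations

from .simulate import FamilySpec, HostParalogSpec, PlantSpec, SdSpec

# pairwise identity within a family is roughly (1 - rate)^2; the rates
# below span the ~0.95-0.99 pairwise band the self-aligner targets
FAMILY_DISCOVERY_FAMILIES = (
    FamilySpec("teA", 1500, 40, 0.005, 0.0005, te_class="LINE"),
    FamilySpec("teB", 800, 100, 0.0125, 0.0005, te_class="SINE"),
    FamilySpec("teC", 2500, 20, 0.0075, 0.0005, te_class="LTR"),
    FamilySpec("teD", 600, 150, 0.02, 0.0, te_class="DNA"),
    FamilySpec(
        "teE", 3000, 30, 0.005, 0.0,
        truncation_mean_frac=0.15, te_class="LINE",
    ),
)

# ancestors placed in the TE reference library for classification
FAMILY_DISCOVERY_LIBRARY = ("teA", "teB", "teC")


def family_discovery_spec() -> PlantSpec:
    return PlantSpec(
        background_length=600_000,
        gc=0.42,
        families=FAMILY_DISCOVERY_FAMILIES
        + (
            FamilySpec(
                "l2active", 2600, 6, 0.003,
                te_class="LINE", has_intact_orf2=True, rt_protein_length=250,
            ),
        ),
        sds=(
            SdSpec("sd1", 8_000, 2, 0.97),
            SdSpec("sd2", 12_000, 2, 0.98),
            SdSpec("sd3", 18_000, 3, 0.97),
        ),
        host_paralogs=(HostParalogSpec("hostA", 300, 4),),
    )


def high_copy_spec() -> PlantSpec:
    return PlantSpec(
        background_length=450_000,
        gc=0.42,
        families=(
            FamilySpec("hcTE", 300, 2500, 0.005, 0.0, te_class="DNA"),
        ),
        sds=(
            SdSpec("sdA", 6_000, 2, 0.97),
            SdSpec("sdB", 9_000, 3, 0.97),
            SdSpec("sdC", 15_000, 2, 0.98),
        ),
    )
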