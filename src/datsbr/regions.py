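"""Region-of-interest vocabulary shared across the package.

Five bilateral nigrostriatal ROIs are analysed: anterior putamen (AP),
posterior putamen (PP), anterior caudate (AC), posterior caudate (PC) and
substantia nigra (SN). The four caudate/putamen subregions are jointly
referred to as the striatal regions.
"""

REGIONS: tuple[str, ...] = ("AP", "PP", "AC", "PC", "SN")
STRIATAL_REGIONS: tuple[str, ...] = ("AP", "PP", "AC", "PC")

GROUPS: tuple[str, ...] = ("HC", "MCI-LB", "DLB")
PATIENT_GROUPS: tuple[str, ...] = ("MCI-LB", "DLB")

SIDES: tuple[str, ...] = ("L", "R")


def validate_regions(names) -> None:
    """Raise ``ValueError`` unless *names* is exactly the five-ROI set."""
    if set(names) != set(REGIONS):
        raise ValueError(
            f"region set must be exactly {set(REGIONS)}, got {set(names)}"
        )
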