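"""Reference panel of shared core gut taxa.

The 47 species-level taxa found in at least 75% of samples of *both*
the active and the sedentary group of the study cohort.  The panel is
useful as a realistic node set: 47 taxa give exactly 46*(47/2) = 1081
candidate pairs for the all-pairs correlation screen.
"""

OVERLAPPING_CORE_TAXA: tuple[str, ...] = (
    "Bifidobacterium longum",
    "Unclassified Coriobacteriaceae",
    "Unclassified Bacteroides",
    "Bacteroides caccae",
    "Bacteroides eggerthii",
    "Bacteroides ovatus",
    "Bacteroides plebeius",
    "Bacteroides uniformis",
    "Unclassified Parabacteroides",
    "Parabacteroides distasonis",
    "Unclassified Prevotella",
    "Unclassified Rikenellaceae",
    "Unclassified 2 Rikenellaceae",
    "Unclassified Barnesiellaceae",
    "Unclassified Butyricimonas",
    "Unclassified Odoribacter",
    "Unclassified Streptococcus",
    "Unclassified Clostridiales",
    "Unclassified 2 Clostridiales",
    "Unclassified 2 Christensenellaceae",
    "Unclassified Clostridiaceae",
    "Unclassified Clostridium",
    "Unclassified Lachnospiraceae",
    "Unclassified 2 Lachnospiraceae",
    "Unclassified Anaerostipes",
    "Unclassified Blautia",
    "Unclassified Coprococcus",
    "Coprococcus eutactus",
    "Unclassified Dorea",
    "Unclassified Lachnospira",
    "Unclassified Roseburia",
    "Roseburia faecis",
    "Ruminococcus gnavus",
    "Ruminococcus torques",
    "Unclassified Ruminococcaceae",
    "Unclassified 2 Ruminococcaceae",
    "Unclassified Anaerotruncus",
    "Faecalibacterium prausnitzii",
    "Unclassified Oscillospira",
    "Unclassified Ruminococcus",
    "Unclassified Mogibacteriaceae",
    "Unclassified Erysipelotrichaceae",
    "Unclassified Holdemania",
    "Unclassified Sutterella",
    "Unclassified Bilophila",
    "Unclassified Enterobacteriaceae",
    "Unclassified RF39",
)
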