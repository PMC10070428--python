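name	state	provenance
acetaminophen	permeable	literature
acetaminophen+oxycodone	permeable	literature
acetaminophen+hydrocodone	permeable	literature
morphine	permeable	literature
pregabalin	permeable	literature
gabapentin	permeable	literature
oxycodone	permeable	literature
hydrocodone	permeable	literature
fentanyl	permeable	literature
codeine	permeable	literature
ibuprofen	permeable	literature
ketorolac	permeable	literature
naproxen	permeable	literature
diazepam	permeable	literature
lorazepam	permeable	literature
midazolam	permeable	literature
baclofen	permeable	literature
amitriptyline	permeable	literature
sertraline	permeable	literature
fluoxetine	permeable	literature
trazodone	permeable	literature
haloperidol	permeable	literature
phenytoin	permeable	literature
carbamazepine	permeable	literature
valproate	permeable	literature
metoclopramide	permeable	literature
diphenhydramine	permeable	literature
promethazine	permeable	literature
ondansetron	permeable	literature
ciprofloxacin	permeable	literature
metronidazole	permeable	literature
nicotine	permeable	literature
nitroglycerin	permeable	literature
propranolol	permeable	literature
clonidine	permeable	literature
isoflurane	permeable	literature
ketamine	permeable	literature
propofol	permeable	literature
zolpidem	permeable	literature
oxybutynin	permeable	literature
heparin	not_permeable	literature
enoxaparin	not_permeable	literature
warfarin	not_permeable	literature
docusate	not_permeable	literature
senna	not_permeable	literature
bisacodyl	not_permeable	literature
polyethylene glycol	not_permeable	literature
ranitidine	not_permeable	literature
famotidine	not_permeable	literature
omeprazole	not_permeable	literature
sucralfate	not_permeable	literature
cefazolin	not_permeable	literature
ceftriaxone	not_permeable	unreviewed
gentamicin	not_permeable	literature
vancomycin	not_permeable	literature
nitrofurantoin	not_permeable	unreviewed
amoxicillin	not_permeable	unreviewed
piperacillin	not_permeable	unreviewed
dopamine	not_permeable	literature
norepinephrine	not_permeable	literature
phenylephrine	not_permeable	unreviewed
vecuronium	not_permeable	literature
rocuronium	not_permeable	unreviewed
insulin	not_permeable	literature
furosemide	not_permeable	literature
potassium chloride	not_permeable	literature
magnesium hydroxide	not_permeable	unreviewed
aluminum hydroxide	not_permeable	unreviewed
calcium carbonate	not_permeable	unreviewed
albuterol	permeable	unreviewed
ipratropium	not_permeable	unreviewed
acetylcysteine	not_permeable	unreviewed
epoetin	not_permeable	unreviewed
ferrous sulfate	not_permeable	unreviewed
multivitamin	unknown	unreviewed
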