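# USAN name stems: kind in {prefix, infix, suffix}.
# stem<TAB>kind<TAB>definition
-tide	suffix	peptides and glycopeptides
-mab	suffix	monoclonal antibodies
-stat	suffix	enzyme inhibitors
-vastatin	suffix	HMG-CoA reductase inhibitors
-olol	suffix	beta-blockers
-oxacin	suffix	quinolone antibacterials
-cillin	suffix	penicillins
-azepam	suffix	antianxiety agents (diazepam type)
-tinib	suffix	tyrosine kinase inhibitors
-ciclib	suffix	cyclin-dependent kinase inhibitors
-lisib	suffix	phosphatidylinositol 3-kinase inhibitors
-prazole	suffix	antiulcer agents (benzimidazole type)
-sartan	suffix	angiotensin II receptor antagonists
-pril	suffix	ACE inhibitors
-gliflozin	suffix	sodium glucose cotransporter inhibitors
-gliptin	suffix	dipeptidyl peptidase IV inhibitors
-lukast	suffix	leukotriene antagonists
-navir	suffix	HIV protease inhibitors
-vir	suffix	antivirals
-azole	suffix	antifungals (systemic miconazole type)
-caine	suffix	local anesthetics
-dipine	suffix	calcium channel blockers (nifedipine type)
-profen	suffix	anti-inflammatory agents (ibuprofen type)
-setron	suffix	serotonin 5-HT3 receptor antagonists
-triptan	suffix	serotonin 5-HT1 receptor agonists
-parib	suffix	poly(ADP-ribose) polymerase inhibitors
-degib	suffix	hedgehog signaling pathway inhibitors
-rafenib	suffix	RAF kinase inhibitors
-metinib	suffix	MEK kinase inhibitors
-zomib	suffix	proteasome inhibitors
-lutamide	suffix	nonsteroidal antiandrogens
-dopa	suffix	dopamine receptor agonists
cef-	prefix	cephalosporins
sulfa-	prefix	antimicrobials (sulfonamide type)
arte-	prefix	artemisinin-derived antimalarials
-io-	infix	iodine-containing contrast media
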