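{
 "Akkermansia muciniphila": {"taxid": "239935", "retrieved_at": "2025-01-15T00:00:00Z"},
 "Bacillus subtilis": {"taxid": "1423", "retrieved_at": "2025-01-15T00:00:00Z"},
 "Bacteroides fragilis": {"taxid": "817", "retrieved_at": "2025-01-15T00:00:00Z"},
 "Bacteroides thetaiotaomicron": {"taxid": "818", "retrieved_at": "2025-01-15T00:00:00Z"},
 "Bacteroides uniformis": {"taxid": "820", "retrieved_at": "2025-01-15T00:00:00Z"},
 "Bacteroides vulgatus": {"taxid": "821", "retrieved_at": "2025-01-15T00:00:00Z"},
 "Bifidobacterium adolescentis": {"taxid": "1680", "retrieved_at": "2025-01-15T00:00:00Z"},
 "Bifidobacterium bifidum": {"taxid": "1681", "retrieved_at": "2025-01-15T00:00:00Z"},
 "Bifidobacterium longum": {"taxid": "216816", "retrieved_at": "2025-01-15T00:00:00Z"},
 "Butyrivibrio fibrisolvens": {"taxid": "831", "retrieved_at": "2025-01-15T00:00:00Z"},
 "Campylobacter jejuni": {"taxid": "197", "retrieved_at": "2025-01-15T00:00:00Z"},
 "Clostridioides difficile": {"taxid": "1496", "retrieved_at": "2025-01-15T00:00:00Z"},
 "Clostridium butyricum": {"taxid": "1492", "retrieved_at": "2025-01-15T00:00:00Z"},
 "Enterococcus faecalis": {"taxid": "1351", "retrieved_at": "2025-01-15T00:00:00Z"},
 "Enterococcus faecium": {"taxid": "1352", "retrieved_at": "2025-01-15T00:00:00Z"},
 "Escherichia coli": {"taxid": "562", "retrieved_at": "2025-01-15T00:00:00Z"},
 "Eubacterium hallii": {"taxid": "39488", "retrieved_at": "2025-01-15T00:00:00Z"},
 "Eubacterium rectale": {"taxid": "39491", "retrieved_at": "2025-01-15T00:00:00Z"},
 "Faecalibacterium prausnitzii": {"taxid": "853", "retrieved_at": "2025-01-15T00:00:00Z"},
 "Fusobacterium nucleatum": {"taxid": "851", "retrieved_at": "2025-01-15T00:00:00Z"},
 "Haemophilus influenzae": {"taxid": "727", "retrieved_at": "2025-01-15T00:00:00Z"},
 "Helicobacter pylori": {"taxid": "210", "retrieved_at": "2025-01-15T00:00:00Z"},
 "Klebsiella pneumoniae": {"taxid": "573", "retrieved_at": "2025-01-15T00:00:00Z"},
 "Lactiplantibacillus plantarum": {"taxid": "1590", "retrieved_at": "2025-01-15T00:00:00Z"},
 "Lactobacillus acidophilus": {"taxid": "1579", "retrieved_at": "2025-01-15T00:00:00Z"},
 "Lactococcus lactis": {"taxid": "1358", "retrieved_at": "2025-01-15T00:00:00Z"},
 "Listeria monocytogenes": {"taxid": "1639", "retrieved_at": "2025-01-15T00:00:00Z"},
 "Methanobrevibacter smithii": {"taxid": "2173", "retrieved_at": "2025-01-15T00:00:00Z"},
 "Mycobacterium tuberculosis": {"taxid": "1773", "retrieved_at": "2025-01-15T00:00:00Z"},
 "Parabacteroides distasonis": {"taxid": "823", "retrieved_at": "2025-01-15T00:00:00Z"},
 "Prevotella copri": {"taxid": "165179", "retrieved_at": "2025-01-15T00:00:00Z"},
 "Pseudomonas aeruginosa": {"taxid": "287", "retrieved_at": "2025-01-15T00:00:00Z"},
 "Roseburia hominis": {"taxid": "301301", "retrieved_at": "2025-01-15T00:00:00Z"},
 "Roseburia intestinalis": {"taxid": "166486", "retrieved_at": "2025-01-15T00:00:00Z"},
 "Ruminococcus bromii": {"taxid": "40518", "retrieved_at": "2025-01-15T00:00:00Z"},
 "Ruminococcus gnavus": {"taxid": "33038", "retrieved_at": "2025-01-15T00:00:00Z"},
 "Ruminococcus torques": {"taxid": "33039", "retrieved_at": "2025-01-15T00:00:00Z"},
 "Salmonella enterica": {"taxid": "28901", "retrieved_at": "2025-01-15T00:00:00Z"},
 "Staphylococcus aureus": {"taxid": "1280", "retrieved_at": "2025-01-15T00:00:00Z"},
 "Streptococcus pneumoniae": {"taxid": "1313", "retrieved_at": "2025-01-15T00:00:00Z"},
 "Streptococcus pyogenes": {"taxid": "1314", "retrieved_at": "2025-01-15T00:00:00Z"},
 "Streptococcus thermophilus": {"taxid": "1308", "retrieved_at": "2025-01-15T00:00:00Z"},
 "Vibrio cholerae": {"taxid": "666", "retrieved_at": "2025-01-15T00:00:00Z"}
}
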