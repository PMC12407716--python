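pathway	superclass
Terpenoids	Sesquiterpenoids
Terpenoids	Monoterpenoids
Terpenoids	Diterpenoids
Terpenoids	Meroterpenoids
Terpenoids	Apocarotenoids
Terpenoids	Steroids
Terpenoids	Triterpenoids
Terpenoids	Carotenoids (C40)
Shikimates and Phenylpropanoids	Coumarins
Shikimates and Phenylpropanoids	Flavonoids
Shikimates and Phenylpropanoids	Lignans
Shikimates and Phenylpropanoids	Phenolic acids (C6-C1)
Shikimates and Phenylpropanoids	Phenylpropanoids (C6-C3)
Shikimates and Phenylpropanoids	Stilbenoids
Shikimates and Phenylpropanoids	Styrylpyrones
Shikimates and Phenylpropanoids	Phenanthrenoids
Alkaloids	Tryptophan alkaloids
Alkaloids	Anthranilic acid alkaloids
Alkaloids	Nicotinic acid alkaloids
Alkaloids	Tyrosine alkaloids
Alkaloids	Lysine alkaloids
Alkaloids	Ornithine alkaloids
Alkaloids	Pseudoalkaloids
Alkaloids	Peptide alkaloids
Amino acids and Peptides	Small peptides
Amino acids and Peptides	Amino acids
Fatty acids	Fatty Acids and Conjugates
Fatty acids	Fatty esters
Polyketides	Macrolides
Polyketides	Aromatic polyketides
Carbohydrates	Saccharides
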