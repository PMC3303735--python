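# Breast-lesion morphology term tree (synthetic fixture).
# Nested term list: two spaces of indent per level, "term_id<TAB>name".
# Codes follow the axis-letter + 5-digit surface form of morphology axes;
# they are lexicon entries for this package, not asserted against any
# terminology release.
M-80000	Neoplasm and hamartoma
  M-80001	Neoplasm benign
    M-90100	Fibroadenoma
      M-90110	Intracanalicular fibroadenoma
      M-90120	Pericanalicular fibroadenoma
      M-90160	Giant fibroadenoma
    M-85060	Intraductal papilloma
    M-85050	Intraductal papillomatosis
    M-81400	Adenoma
      M-82040	Lactating adenoma
      M-82110	Tubular adenoma
      M-89400	Pleomorphic adenoma
    M-88500	Lipoma
    M-89040	Adenolipoma
    M-91200	Hemangioma
    M-93000	Adenomyoepithelioma
    M-75500	Hamartoma of breast
  M-80009	Neoplasm of uncertain behavior
    M-90200	Phyllodes tumor
    M-85030	Atypical ductal hyperplasia
    M-85200	Atypical lobular hyperplasia
  M-80003	Neoplasm malignant
    M-80103	Carcinoma not otherwise specified
    M-81403	Adenocarcinoma not otherwise specified
    M-85003	Infiltrating duct carcinoma
      M-85013	Comedocarcinoma
      M-85073	Invasive micropapillary carcinoma
      M-85233	Infiltrating duct mixed with other types
    M-85002	Intraductal carcinoma noninfiltrating
      M-85012	Comedocarcinoma noninfiltrating
      M-85032	Intraductal papillary carcinoma
    M-85203	Lobular carcinoma invasive
    M-85202	Lobular carcinoma in situ
    M-84803	Mucinous adenocarcinoma
    M-85103	Medullary carcinoma
    M-82113	Tubular carcinoma
    M-85753	Metaplastic carcinoma
    M-85403	Paget disease mammary
    M-85413	Paget disease and infiltrating duct carcinoma
    M-90203	Phyllodes tumor malignant
    M-88003	Sarcoma not otherwise specified
    M-91203	Angiosarcoma
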