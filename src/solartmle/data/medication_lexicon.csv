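drug_class,agent,category
Short-acting beta2-agonists (SABA),terbutaline,reliever
Short-acting beta2-agonists (SABA),salbuatmol,reliever
Short-acting beta2-agonists (SABA),salbutamol,reliever
Short-acting beta2-agonists (SABA),tulobuterol,reliever
Short-acting beta2-agonists (SABA),fenoterol,reliever
Short-acting beta2-agonists (SABA),epinephrine,reliever
Short-acting beta2-agonists (SABA),adrenaline,reliever
Combinations of SABA and mast-cell stabilizers,reproterol + sodiumcromoglicat,reliever
Combinations of SABA and mast-cell stabilizers,fenoterol + cromoglicic acid,reliever
Short-acting muscarinic antagonists (SAMA),ipratropium bromide,reliever
Combinations of SABA and SAMA,fenoterol + ipratropium bromide,reliever
Inhaled corticosteroids (ICS),beclomethasone,control
Inhaled corticosteroids (ICS),fluticasone,control
Inhaled corticosteroids (ICS),budesonide,control
Inhaled corticosteroids (ICS),dexamethasone,control
Inhaled corticosteroids (ICS),flunisolide,control
Long-acting beta2-agonists (LABA),formoterol,control
Long-acting beta2-agonists (LABA),salmeterol,control
Long-acting beta2-agonists (LABA),clenbuterol,control
Combinations of ICS and LABA,fluticasone + salmeterol,control
Combinations of ICS and LABA,formoterol + budesonide,control
Leukotriene receptor antagonists,montelukast,control
Systemic corticosteroids,betamethasone,control
Systemic corticosteroids,cortisone,control
Systemic corticosteroids,prednisone,control
Systemic corticosteroids,prednisolone,control
Systemic corticosteroids,mometasone,control
Mast-cell-stabilizer,cromocligic acid,control
Mast-cell-stabilizer,cromoglicic acid,control
Methylxanthines,methylxanthines,control
Methylxanthines,aminophylline,control
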