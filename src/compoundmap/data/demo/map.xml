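<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2/version4" xmlns:celldesigner="http://www.sbml.org/2001/ns/celldesigner" level="2" version="4">
  <model id="demo_cftr_excerpt" name="Synthetic CFTR lifecycle excerpt">
    <listOfCompartments>
      <compartment id="pm" name="plasma membrane"/>
      <compartment id="er" name="endoplasmic reticulum"/>
      <compartment id="cytosol" name="cytosol"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="s1" name="CFTR" compartment="pm">
        <annotation>
          <celldesigner:extension>
            <celldesigner:speciesIdentity>
              <celldesigner:class>PROTEIN</celldesigner:class>
            </celldesigner:speciesIdentity>
          </celldesigner:extension>
        </annotation>
      </species>
      <species id="s2" name="CFTR" compartment="er">
        <annotation>
          <celldesigner:extension>
            <celldesigner:speciesIdentity>
              <celldesigner:class>PROTEIN</celldesigner:class>
            </celldesigner:speciesIdentity>
          </celldesigner:extension>
        </annotation>
      </species>
      <species id="s3" name="HSP90AA1" compartment="cytosol">
        <annotation>
          <celldesigner:extension>
            <celldesigner:speciesIdentity>
              <celldesigner:class>PROTEIN</celldesigner:class>
            </celldesigner:speciesIdentity>
          </celldesigner:extension>
        </annotation>
      </species>
      <species id="s4" name="KEAP1" compartment="cytosol">
        <annotation>
          <celldesigner:extension>
            <celldesigner:speciesIdentity>
              <celldesigner:class>PROTEIN</celldesigner:class>
            </celldesigner:speciesIdentity>
          </celldesigner:extension>
        </annotation>
      </species>
      <species id="s5" name="TGFB1" compartment="cytosol">
        <annotation>
          <celldesigner:extension>
            <celldesigner:speciesIdentity>
              <celldesigner:class>PROTEIN</celldesigner:class>
            </celldesigner:speciesIdentity>
          </celldesigner:extension>
        </annotation>
      </species>
      <species id="m1" name="ATP" compartment="cytosol"/>
    </listOfSpecies>
  </model>
</sbml>
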